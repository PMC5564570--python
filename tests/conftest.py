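import logging

import numpy as np
import pandas as pd
import pytest

from rmodm import BetaMatrix
from rmodm.pipeline import PipelineConfig, run_pipeline
from rmodm.synthetic import SimConfig, simulate_cohort

logging.getLogger("rmodm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study conditions."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default cohort (shared across tests)."""
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(seed=11)
    summary = run_pipeline(cfg, out)
    return cfg, out, summary


def toy_matrix(values, site_ids=None, sample_ids=None, group="normal"):
    arr = np.asarray(values, dtype=float)
    site_ids = site_ids or [f"s{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"c{j}" for j in range(arr.shape[1])]
    return BetaMatrix(
        pd.DataFrame(arr, index=site_ids, columns=sample_ids),
        pd.Series(group, index=sample_ids, dtype=object),
    )


@pytest.fixture
def make_matrix():
    return toy_matrix
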