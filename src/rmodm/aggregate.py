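"""Gene-level DM states per sample and cross-sample frequency classes.

A gene is DM in a sample when at least one promoter CpG is called DM; a
gene whose promoter carries both hyper and hypo calls in the same sample
is *inconsistent* and contributes to neither direction.  Per-gene
frequencies over the cohort then separate *universal* genes (DM in more
than 95% of samples, one direction) from *heterogeneous* ones (20-80%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import HYPER, HYPO
from .rankcomp import NONE

log = logging.getLogger(__name__)

INCONSISTENT = "inconsistent"

UNIVERSAL_HYPER = "universal_hyper"
UNIVERSAL_HYPO = "universal_hypo"
HETEROGENEOUS = "heterogeneous"
RARE = "rare"


@dataclass
class GeneDMMatrix:
    """Per-(sample, gene) DM states plus cohort-level frequencies."""

    states: pd.DataFrame       # long: sample_id, gene, state
    n_samples: int             # frequency denominator (all cohort samples)

    def frequencies(self) -> pd.DataFrame:
        """Per-gene hyper/hypo/inconsistent/none fractions (sum to 1)."""
        counts = (
            self.states.pivot_table(index="gene", columns="state",
                                    values="sample_id", aggfunc="count",
                                    fill_value=0)
            .reindex(columns=[HYPER, HYPO, INCONSISTENT], fill_value=0)
        )
        freq = counts / self.n_samples
        freq.columns = ["hyper_freq", "hypo_freq", "inconsistent_freq"]
        freq["none_freq"] = 1.0 - freq.sum(axis=1)
        return freq


def genes_from_sites(
    calls: pd.DataFrame,
    annotation: pd.Series,
    sample_ids: list[str] | None = None,
) -> GeneDMMatrix:
    """Lift site-level DM calls to per-sample gene states.

    Gene state per sample: ``hyper`` if >= 1 promoter CpG is called hyper
    and none hypo, symmetric for ``hypo``, ``inconsistent`` if both
    directions occur (excluded from both frequencies).  Calls on probes
    without a gene annotation are dropped with a logged count.
    ``sample_ids`` fixes the frequency denominator; it defaults to the
    samples appearing in ``calls``.
    """
    if sample_ids is None:
        sample_ids = list(pd.unique(calls["sample_id"])) if len(calls) else []
    dm = calls[calls["direction"].isin([HYPER, HYPO])].copy()
    genes = annotation.reindex(dm["site_id"])
    n_unannotated = int(genes.isna().sum())
    if n_unannotated:
        log.warning("%d DM calls on unannotated probes ignored", n_unannotated)
    dm["gene"] = genes.to_numpy()
    dm = dm.dropna(subset=["gene"])
    if dm.empty:
        states = pd.DataFrame(columns=["sample_id", "gene", "state"])
        return GeneDMMatrix(states, len(sample_ids))
    flags = (
        dm.assign(is_hyper=dm["direction"] == HYPER,
                  is_hypo=dm["direction"] == HYPO)
        .groupby(["sample_id", "gene"])[["is_hyper", "is_hypo"]].any()
        .reset_index()
    )
    state = np.select(
        [flags["is_hyper"] & flags["is_hypo"], flags["is_hyper"], flags["is_hypo"]],
        [INCONSISTENT, HYPER, HYPO],
        default=NONE,
    )
    states = flags.assign(state=state)[["sample_id", "gene", "state"]]
    return GeneDMMatrix(states, len(sample_ids))


def classify_frequency(
    matrix: GeneDMMatrix,
    universal: float = 0.95,
    hetero: tuple[float, float] = (0.20, 0.80),
) -> pd.DataFrame:
    """Per-gene frequency class from cohort DM frequencies.

    ``universal_hyper``/``universal_hypo`` require a frequency strictly
    above ``universal`` ("more than 95%"); ``heterogeneous`` requires
    either direction's frequency inside the closed ``hetero`` interval;
    everything else is ``rare``.  Sample order never matters.
    """
    if matrix.n_samples < 1:
        raise ValueError("need at least one sample to classify gene frequencies")
    freq = matrix.frequencies()
    lo, hi = hetero
    in_band = (
        freq["hyper_freq"].between(lo, hi) | freq["hypo_freq"].between(lo, hi)
    )
    cls = np.select(
        [freq["hyper_freq"] > universal, freq["hypo_freq"] > universal, in_band],
        [UNIVERSAL_HYPER, UNIVERSAL_HYPO, HETEROGENEOUS],
        default=RARE,
    )
    out = freq.copy()
    out["class"] = cls
    return out
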