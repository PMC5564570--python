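"""Signal-to-beta conversion and cross-platform probe restriction.

Illumina arrays report a methylated (M) and unmethylated (U) intensity per
probe; the methylation level is summarised as the beta value
``M / (U + M + 100)``, where the +100 offset regularises low-intensity
probes.  Analyses that pool 27K and 450K cohorts are restricted to the
probes shared by both platforms.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, BetaMatrixError

BETA_OFFSET = 100.0


def beta_value(M, U):
    """Beta value ``M / (U + M + 100)`` from signal intensities.

    Accepts scalars or arrays; both intensities must be non-negative.
    The result lies in [0, 1) and is strictly increasing in M for fixed U
    and strictly decreasing in U for fixed M.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("signal intensities must be non-negative")
    out = M / (U + M + BETA_OFFSET)
    return float(out) if out.ndim == 0 else out


def beta_from_intensities(M: pd.DataFrame, U: pd.DataFrame,
                          groups=None) -> BetaMatrix:
    """Build a :class:`BetaMatrix` from aligned M and U intensity frames."""
    if not M.index.equals(U.index) or not M.columns.equals(U.columns):
        raise BetaMatrixError("M and U matrices must share sites and samples")
    vals = pd.DataFrame(
        beta_value(M.to_numpy(float), U.to_numpy(float)),
        index=M.index, columns=M.columns,
    )
    return BetaMatrix(vals, groups)


def intersect_probes(matrices: Sequence[BetaMatrix]) -> list[BetaMatrix]:
    """Restrict matrices to their common probes (sorted intersection).

    All returned matrices share one identical ordered site list; sample
    columns are untouched.  An empty intersection is an error.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].site_ids)
    for m in matrices[1:]:
        common &= set(m.site_ids)
    if not common:
        sizes = [m.n_sites for m in matrices]
        raise BetaMatrixError(
            f"no probes shared by the {len(matrices)} matrices "
            f"(sizes {sizes}); cannot restrict to a common core"
        )
    shared = sorted(common)
    return [m.subset_sites(shared) for m in matrices]
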