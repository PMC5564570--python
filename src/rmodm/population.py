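"""Population-level differential methylation between tumor and normal groups.

A per-site two-sample t-test (Welch by default) with Benjamini-Hochberg
adjustment gives each cohort a list of significant sites; the candidate
set for individualized calling is the sites significant in *two*
independent cohorts with the same direction of change (direction taken
from the difference of group mean beta values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import BetaMatrix

HYPER = "hyper"
HYPO = "hypo"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def ttest_dm(
    dataset: BetaMatrix,
    fdr: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-site tumor-vs-normal t-test with BH adjustment.

    Returns a frame indexed by site with columns ``t, p, q, direction,
    tested, significant``.  Direction is the sign of
    ``mean(tumor) - mean(normal)`` on the beta scale (``hyper``/``hypo``).
    Sites with fewer than two non-missing values in either group are
    marked untested and never significant.
    """
    if dataset.groups is None:
        raise ValueError("dataset needs per-sample group labels")
    g = dataset.groups
    tumor_cols = g[g == "tumor"].index
    normal_cols = g[g.isin(["normal", "adjacent_normal"])].index
    if len(tumor_cols) == 0 or len(normal_cols) == 0:
        raise ValueError("dataset must contain both tumor and normal samples")
    xt = dataset.values[tumor_cols].to_numpy(float)
    xn = dataset.values[normal_cols].to_numpy(float)
    tested = (np.sum(~np.isnan(xt), axis=1) >= 2) & (np.sum(~np.isnan(xn), axis=1) >= 2)
    t = np.full(dataset.n_sites, np.nan)
    p = np.full(dataset.n_sites, np.nan)
    if tested.any():
        res = stats.ttest_ind(
            xt[tested], xn[tested], axis=1, equal_var=equal_var, nan_policy="omit"
        )
        t[tested] = res.statistic
        p[tested] = res.pvalue
    # constant-input sites can still yield NaN statistics; drop them from the family
    tested &= ~np.isnan(p)
    q = np.full(dataset.n_sites, np.nan)
    q[tested] = bh_adjust(p[tested])
    with np.errstate(invalid="ignore"):
        diff = np.nanmean(xt, axis=1) - np.nanmean(xn, axis=1)
    direction = np.where(diff > 0, HYPER, HYPO)
    significant = tested & (q < fdr)
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "direction": direction,
            "tested": tested,
            "significant": significant,
        },
        index=pd.Index(dataset.site_ids, name="probe_id"),
    )


@dataclass
class ConcordantCandidates:
    """Sites significant in both cohorts, split by direction agreement."""

    candidates: pd.DataFrame     # index site, column 'direction'
    n_overlap: int               # significant in both, any direction
    n_discordant: int
    concordant_fraction: float   # among overlapping significant sites

    @property
    def sites(self) -> list[str]:
        return list(self.candidates.index)


def intersect_concordant(resA: pd.DataFrame, resB: pd.DataFrame) -> ConcordantCandidates:
    """Candidate sites: significant in both cohorts with matching direction.

    Discordant overlaps (significant in both but with opposite directions)
    are excluded from the candidates and reported with their count and
    fraction.  Symmetric in its two arguments.
    """
    sigA = resA[resA["significant"]]
    sigB = resB[resB["significant"]]
    overlap = sigA.index.intersection(sigB.index)
    same = sigA.loc[overlap, "direction"] == sigB.loc[overlap, "direction"]
    cand = pd.DataFrame({"direction": sigA.loc[overlap[same.to_numpy()], "direction"]})
    cand.index.name = "probe_id"
    n_overlap = len(overlap)
    n_disc = int((~same).sum())
    frac = float(same.mean()) if n_overlap else float("nan")
    return ConcordantCandidates(cand, n_overlap, n_disc, frac)
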