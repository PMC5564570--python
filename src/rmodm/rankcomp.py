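"""Individual-level differential methylation calls from reversed orderings.

For one cancer sample and one candidate CpG site *c*, every stable partner
of *c* in the normal background is checked: a partner stably *above* c
that is observed *below* c in this sample is a reversal supporting
hypermethylation of c, and a partner stably *below* c observed *above* c
supports hypomethylation.  A two-sided Fisher's exact test on the 2x2
table

    [[r_above, n_above - r_above],
     [r_below, n_below - r_below]]

asks whether the reversal proportions on the two sides differ; under the
null (c unchanged, background intact) both sides reverse at the same
small error rate.  Per sample, p-values are BH-adjusted across the tested
candidates and direction is assigned where q < fdr.

The exact test is evaluated by fixed-margin enumeration with integer
arithmetic (sum of hypergeometric outcomes no more probable than the
observed table), so small-table p-values are exact to the last bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import BetaMatrix
from .population import HYPER, HYPO, bh_adjust
from .stable_pairs import StablePairSet

log = logging.getLogger(__name__)

NONE = "none"


@dataclass
class ReversalCounts:
    """Reversal evidence for one site in one cancer sample."""

    site: int
    n_above: int   # partners stably above the site (usable in this sample)
    n_below: int   # partners stably below
    r_above: int   # above-partners observed below -> support hyper
    r_below: int   # below-partners observed above -> support hypo


def count_reversals(sample: np.ndarray, site: int,
                    pairs: StablePairSet) -> ReversalCounts:
    """Count reversal pairs for ``site`` in one sample column.

    Strict inequalities only: a tied partner is a non-reversal but stays
    in the denominator; a partner with a missing value is dropped from
    both numerator and denominator.  A missing value at the site itself
    leaves every comparison undefined, so all counts are zero (the site
    is untested downstream).
    """
    x = np.asarray(sample, dtype=float)
    if np.isnan(x[site]):
        return ReversalCounts(site, 0, 0, 0, 0)
    above = pairs.partners_above(site)
    below = pairs.partners_below(site)
    va = above[~np.isnan(x[above])]
    vb = below[~np.isnan(x[below])]
    return ReversalCounts(
        site=site,
        n_above=len(va),
        n_below=len(vb),
        r_above=int(np.sum(x[site] > x[va])),
        r_below=int(np.sum(x[vb] > x[site])),
    )


def fisher_reversal_p(r_above: int, n_above: int,
                      r_below: int, n_below: int) -> float:
    """Two-sided Fisher exact p for the reversal 2x2 table.

    Enumerates all tables with the observed margins; the p-value is the
    total probability of outcomes whose hypergeometric probability does
    not exceed the observed one.  Integer arithmetic keeps ties exact.
    """
    if not (0 <= r_above <= n_above and 0 <= r_below <= n_below):
        raise ValueError("reversal counts must satisfy 0 <= r <= n")
    K = r_above + r_below           # total reversals across both sides
    N = n_above + n_below
    if N == 0:
        return 1.0
    lo = max(0, K - n_below)
    hi = min(K, n_above)
    # weight of a table with x reversals on the above side
    obs = comb(n_above, r_above) * comb(n_below, r_below)
    acc = 0
    for x in range(lo, hi + 1):
        w = comb(n_above, x) * comb(n_below, K - x)
        if w <= obs:
            acc += w
    return acc / comb(N, K)


def fisher_dm(counts: ReversalCounts) -> tuple[float, str]:
    """(p, direction hint) for one site's reversal counts.

    The hint compares reversal proportions: ``hyper`` when the above-side
    proportion is larger, ``hypo`` when smaller, ``none`` on a tie.
    """
    p = fisher_reversal_p(counts.r_above, counts.n_above,
                          counts.r_below, counts.n_below)
    pa = counts.r_above / counts.n_above if counts.n_above else 0.0
    pb = counts.r_below / counts.n_below if counts.n_below else 0.0
    if pa > pb:
        hint = HYPER
    elif pa < pb:
        hint = HYPO
    else:
        hint = NONE
    return p, hint


def _counts_for_sample(
    x: np.ndarray,
    cand_idx: np.ndarray,
    pairs: StablePairSet,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vectorized reversal counts for all candidates in one sample.

    ``exclude`` is a boolean site mask of partners to drop from every
    site's counts (the refinement step removes partners already called
    DM, cleaning the comparison background).
    """
    n = pairs.n_sites
    a, b = pairs.a_idx, pairs.b_idx
    valid = ~np.isnan(x[a]) & ~np.isnan(x[b])
    with np.errstate(invalid="ignore"):
        rev = valid & (x[a] > x[b])
    # partner exclusion is role-specific: pair (a,b) serves site a with
    # partner b and site b with partner a
    ok_for_a = valid if exclude is None else valid & ~exclude[b]
    ok_for_b = valid if exclude is None else valid & ~exclude[a]
    n_above = np.bincount(a[ok_for_a], minlength=n)
    r_above = np.bincount(a[ok_for_a & rev], minlength=n)
    n_below = np.bincount(b[ok_for_b], minlength=n)
    r_below = np.bincount(b[ok_for_b & rev], minlength=n)
    site_missing = np.isnan(x[cand_idx])
    df = pd.DataFrame(
        {
            "site_idx": cand_idx,
            "n_above": np.where(site_missing, 0, n_above[cand_idx]),
            "n_below": np.where(site_missing, 0, n_below[cand_idx]),
            "r_above": np.where(site_missing, 0, r_above[cand_idx]),
            "r_below": np.where(site_missing, 0, r_below[cand_idx]),
        }
    )
    return df


def call_sample(
    sample: np.ndarray,
    sample_id: str,
    candidates: list[str],
    pairs: StablePairSet,
    fdr: float = 0.01,
    min_partners: int = 5,
    refine_iters: int = 1,
) -> pd.DataFrame:
    """Call DM CpG sites in one cancer sample.

    Fisher p-values are computed for every testable candidate (at least
    ``min_partners`` usable partners), BH-adjusted within this sample,
    and a direction is assigned where q < fdr.  With ``refine_iters`` > 0
    the pass is repeated with partners called DM in the previous pass
    excluded from every site's counts.
    """
    if not candidates:
        log.warning("sample %s: no candidate sites to test", sample_id)
        return _empty_calls()
    pos = {sid: i for i, sid in enumerate(pairs.site_ids)}
    known = [c for c in candidates if c in pos]
    if len(known) < len(candidates):
        log.warning("sample %s: %d candidates absent from the pair universe",
                    sample_id, len(candidates) - len(known))
    cand_idx = np.array([pos[c] for c in known], dtype=np.int64)
    x = np.asarray(sample, dtype=float)

    exclude: np.ndarray | None = None
    result: pd.DataFrame | None = None
    for _ in range(refine_iters + 1):
        df = _counts_for_sample(x, cand_idx, pairs, exclude)
        df["tested"] = (df["n_above"] + df["n_below"]) >= min_partners
        p = np.ones(len(df))
        hints = np.full(len(df), NONE, dtype=object)
        for i in df.index[df["tested"]]:
            p[i], hints[i] = fisher_dm(ReversalCounts(
                int(df.at[i, "site_idx"]),
                int(df.at[i, "n_above"]), int(df.at[i, "n_below"]),
                int(df.at[i, "r_above"]), int(df.at[i, "r_below"]),
            ))
        df["p"] = np.where(df["tested"], p, np.nan)
        q = np.full(len(df), np.nan)
        tested = df["tested"].to_numpy()
        q[tested] = bh_adjust(p[tested])
        df["q"] = q
        called = tested & (q < fdr) & (hints != NONE)
        df["direction"] = np.where(called, hints, NONE)
        result = df
        new_exclude = np.zeros(pairs.n_sites, dtype=bool)
        new_exclude[df.loc[called, "site_idx"].to_numpy(dtype=np.int64)] = True
        if exclude is not None and np.array_equal(new_exclude, exclude):
            break  # fixed point, further passes cannot change anything
        exclude = new_exclude

    assert result is not None
    out = result.copy()
    out.insert(0, "sample_id", sample_id)
    out.insert(1, "site_id", [pairs.site_ids[i] for i in out["site_idx"]])
    if not out["tested"].any():
        log.warning("sample %s: no testable candidates", sample_id)
    return out.drop(columns="site_idx")[
        ["sample_id", "site_id", "n_above", "n_below", "r_above", "r_below",
         "p", "q", "direction", "tested"]
    ]


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["sample_id", "site_id", "n_above", "n_below", "r_above",
                 "r_below", "p", "q", "direction", "tested"]
    )


def call_cohort(
    tumors: BetaMatrix,
    candidates: list[str],
    pairs: StablePairSet,
    fdr: float = 0.01,
    min_partners: int = 5,
    refine_iters: int = 1,
) -> pd.DataFrame:
    """Independent per-sample DM calls for every tumor column.

    Sample columns are never pooled; a failure in one sample logs a
    warning and the cohort run continues.
    """
    if tumors.n_samples == 0:
        log.warning("empty tumor matrix: no samples to call")
        return _empty_calls()
    # align tumor rows to the pair universe; sites missing from the tumor
    # matrix are treated as missing values
    pos = pd.Index(tumors.site_ids)
    order = pos.get_indexer(pairs.site_ids)
    x_all = tumors.to_numpy()
    frames = []
    for j, sid in enumerate(tumors.sample_ids):
        col = np.where(order >= 0, x_all[np.clip(order, 0, None), j], np.nan)
        try:
            frames.append(call_sample(col, sid, candidates, pairs, fdr,
                                      min_partners, refine_iters))
        except Exception:  # pragma: no cover - defensive per-sample isolation
            log.exception("sample %s failed; continuing cohort", sid)
    return pd.concat(frames, ignore_index=True) if frames else _empty_calls()


def dm_counts_per_sample(calls: pd.DataFrame) -> pd.Series:
    """Number of DM calls (direction != none) per sample."""
    if calls.empty:
        return pd.Series(dtype=int)
    dm = calls[calls["direction"] != NONE]
    counts = dm.groupby("sample_id").size()
    all_samples = calls["sample_id"].unique()
    return counts.reindex(all_samples, fill_value=0).astype(int)


def evaluate_precision(
    calls: pd.DataFrame,
    tumors: BetaMatrix,
    adjacents: BetaMatrix,
    pairing: Mapping[str, str],
    delta_min: float = 0.0,
) -> pd.DataFrame:
    """Precision of per-sample calls against paired adjacent normals.

    The gold standard direction for (sample, site) is the sign of
    ``beta_tumor - beta_adjacent``; differences with absolute value not
    exceeding ``delta_min`` (including exact zero) give no gold direction
    and any call there counts as a false positive.  Returns one row per
    evaluable sample: n_calls, tp, fp, precision.
    """
    dm = calls[calls["direction"] != NONE]
    rows = []
    for sid, grp in dm.groupby("sample_id"):
        if sid not in pairing:
            log.warning("sample %s has no paired adjacent normal; skipped", sid)
            continue
        adj_id = pairing[sid]
        tcol = tumors.values[sid]
        acol = adjacents.values[adj_id]
        diff = tcol.reindex(grp["site_id"]).to_numpy() - \
            acol.reindex(grp["site_id"]).to_numpy()
        called_hyper = (grp["direction"] == HYPER).to_numpy()
        has_gold = np.abs(diff) > delta_min
        tp = int(np.sum(has_gold & np.where(called_hyper, diff > 0, diff < 0)))
        fp = len(grp) - tp
        rows.append({
            "sample_id": sid, "n_calls": len(grp), "tp": tp, "fp": fp,
            "precision": tp / len(grp) if len(grp) else np.nan,
        })
    return pd.DataFrame(rows, columns=["sample_id", "n_calls", "tp", "fp",
                                       "precision"])
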