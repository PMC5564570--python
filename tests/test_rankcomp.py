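"""Reversal counting, the exact reversal-pair test and per-sample calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from rmodm import (
    ReversalCounts,
    call_sample,
    count_reversals,
    evaluate_precision,
    fisher_dm,
    fisher_reversal_p,
)
from rmodm.stable_pairs import StablePairSet


def fisher_oracle(ra, na, rb, nb):
    """Exact-fraction enumeration of fixed-margin tables (p-mass <= observed)."""
    K, N = ra + rb, na + nb
    if N == 0:
        return Fraction(1)
    total = comb(N, K)
    obs = Fraction(comb(na, ra) * comb(nb, rb), total)
    acc = Fraction(0)
    for x in range(max(0, K - nb), min(K, na) + 1):
        w = Fraction(comb(na, x) * comb(nb, K - x), total)
        if w <= obs:
            acc += w
    return acc


def chain_pairs(n, f=0.99, n_samples=10):
    """All pairs (i, j), i < j, over an increasing chain of n sites."""
    a, b = zip(*[(i, j) for i in range(n) for j in range(i + 1, n)])
    return StablePairSet([f"s{i}" for i in range(n)],
                         np.array(a), np.array(b), f, n_samples)


def test_no_reversals_in_a_normal_like_sample():
    pairs = chain_pairs(5)
    x = np.linspace(0.1, 0.5, 5)  # respects every stable ordering
    rc = count_reversals(x, 2, pairs)
    assert (rc.r_above, rc.r_below) == (0, 0)
    assert (rc.n_above, rc.n_below) == (2, 2)


def test_raised_site_reverses_its_above_partners():
    n = 11
    pairs = chain_pairs(n)
    x = np.linspace(0.1, 0.9, n)
    x[0] = 0.85  # raised above 9 of its 10 stably-above partners
    rc = count_reversals(x, 0, pairs)
    assert rc.n_above == 10 and rc.r_above == 9
    assert rc.n_below == 0 and rc.r_below == 0


def test_counts_match_per_pair_loop_oracle():
    rng = np.random.default_rng(33)
    n = 12
    a, b = [], []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                a.append(i), b.append(j)
    pairs = StablePairSet([f"s{i}" for i in range(n)],
                          np.array(a), np.array(b), 0.9, 10)
    x = rng.uniform(size=n)
    x[3] = np.nan
    for c in range(n):
        rc = count_reversals(x, c, pairs)
        na = ra = nb = rb = 0
        for pa, pb in zip(a, b):
            if np.isnan(x[pa]) or np.isnan(x[pb]):
                continue  # missing partner drops from both counts
            if pa == c:
                na += 1
                ra += x[c] > x[pb]
            if pb == c:
                nb += 1
                rb += x[pa] > x[c]
        if np.isnan(x[c]):
            na = ra = nb = rb = 0
        assert (rc.n_above, rc.r_above, rc.n_below, rc.r_below) == (na, ra, nb, rb)


def test_ties_are_non_reversals():
    pairs = chain_pairs(3)
    x = np.array([0.5, 0.5, 0.9])
    rc = count_reversals(x, 0, pairs)
    assert rc.n_above == 2 and rc.r_above == 0


@pytest.mark.parametrize(
    "ra, na, rb, nb, expected_p, expected_hint",
    [
        (0, 10, 0, 10, 1.0, "none"),
        (9, 10, 0, 10, 20 / 167960, "hyper"),
    ],
)
def test_fisher_worked_cases(ra, na, rb, nb, expected_p, expected_hint):
    p, hint = fisher_dm(ReversalCounts(0, na, nb, ra, rb))
    assert p == pytest.approx(expected_p, abs=1e-15)
    assert hint == expected_hint


def test_fisher_agrees_with_scipy_cross_check():
    rng = np.random.default_rng(5)
    for _ in range(60):
        na, nb = rng.integers(1, 40, size=2)
        ra, rb = rng.integers(0, na + 1), rng.integers(0, nb + 1)
        p = fisher_reversal_p(ra, na, rb, nb)
        ref = fisher_exact([[ra, na - ra], [rb, nb - rb]]).pvalue
        assert p == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_symmetry_and_hint_flip():
    p1, h1 = fisher_dm(ReversalCounts(0, 12, 8, 7, 1))
    p2, h2 = fisher_dm(ReversalCounts(0, 8, 12, 1, 7))
    assert p1 == pytest.approx(p2, abs=1e-15)
    assert (h1, h2) == ("hyper", "hypo")


def test_fisher_monotone_in_signal():
    """With r_below = 0 fixed, more above-reversals never weaken the p."""
    prev = 1.1
    for ra in range(0, 11):
        p = fisher_reversal_p(ra, 10, 0, 10)
        assert p <= prev + 1e-15
        prev = p


def test_fisher_degenerate_margins():
    assert fisher_reversal_p(0, 0, 3, 10) == pytest.approx(
        float(fisher_oracle(0, 0, 3, 10)), abs=1e-15
    )
    assert fisher_reversal_p(0, 0, 0, 0) == 1.0


def _null_sample_calls(n=30, seed=0, **kw):
    rng = np.random.default_rng(seed)
    pairs = chain_pairs(n)
    x = np.sort(rng.uniform(0.05, 0.95, size=n))  # order-respecting sample
    cand = [f"s{i}" for i in range(n)]
    return call_sample(x, "t0", cand, pairs, **kw)


def test_call_sample_null_is_quiet_and_refinement_fixed_point():
    base = _null_sample_calls(refine_iters=0)
    refined = _null_sample_calls(refine_iters=1)
    assert (base["direction"] == "none").all()
    # no calls to remove: refinement must be a no-op
    for col in base.columns:
        assert base[col].tolist() == refined[col].tolist()


def test_call_sample_min_partners_marks_untested():
    pairs = chain_pairs(4)  # end sites have 3 partners only
    x = np.linspace(0.2, 0.8, 4)
    out = call_sample(x, "t0", ["s0", "s1", "s2", "s3"], pairs, min_partners=5)
    assert not out["tested"].any()
    assert (out["direction"] == "none").all()


def test_call_sample_unknown_candidate_site_is_skipped():
    pairs = chain_pairs(4)
    out = call_sample(np.linspace(0.1, 0.7, 4), "t0", ["nope"], pairs)
    assert len(out) == 0


def test_planted_disruption_is_called_with_direction():
    rng = np.random.default_rng(2)
    n = 60
    pairs = chain_pairs(n, n_samples=40)
    x = np.sort(rng.uniform(0.05, 0.95, size=n))
    c = 30
    x[c] = x[-3] + 1e-4  # push site far up: most above-partners reverse
    out = call_sample(x, "t0", [f"s{c}"], pairs, fdr=0.01)
    row = out.iloc[0]
    assert row["direction"] == "hyper"
    assert row["r_above"] > 0 and row["r_below"] == 0


def test_evaluate_precision_counts_and_zero_diff_rule(make_matrix):
    import pandas as pd

    calls = pd.DataFrame({
        "sample_id": ["t0"] * 3,
        "site_id": ["s0", "s1", "s2"],
        "direction": ["hyper", "hypo", "hyper"],
    })
    tumors = make_matrix([[0.8], [0.2], [0.5]], sample_ids=["t0"], group="tumor")
    adj = make_matrix([[0.5], [0.5], [0.5]], sample_ids=["a0"],
                      group="adjacent_normal")
    rep = evaluate_precision(calls, tumors, adj, {"t0": "a0"})
    row = rep.iloc[0]
    # s0 hyper matches +0.3; s1 hypo matches -0.3; s2 has zero difference -> FP
    assert (row["tp"], row["fp"]) == (2, 1)
    assert row["precision"] == pytest.approx(2 / 3)


def test_evaluate_precision_skips_unpaired_samples(make_matrix):
    import pandas as pd

    calls = pd.DataFrame({
        "sample_id": ["t0", "t1"],
        "site_id": ["s0", "s0"],
        "direction": ["hyper", "hyper"],
    })
    tumors = make_matrix([[0.8, 0.9]], sample_ids=["t0", "t1"], group="tumor")
    adj = make_matrix([[0.5]], sample_ids=["a0"], group="adjacent_normal")
    rep = evaluate_precision(calls, tumors, adj, {"t0": "a0"})
    assert rep["sample_id"].tolist() == ["t0"]
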