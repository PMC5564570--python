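"""Stable RMO pair mining and cross-list concordance statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from rmodm import binomial_tail_p, concordance, find_stable_pairs
from rmodm.stable_pairs import (
    StablePairSet,
    read_stable_pairs,
    stability_threshold,
    write_stable_pairs,
)


def oracle_pairs(x, f):
    """Exhaustive double loop over all ordered site pairs."""
    n, N = x.shape
    need = stability_threshold(f, N)
    out = set()
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            count = int(np.sum(x[a] < x[b]))  # NaN and ties support neither
            if count >= need:
                out.add((a, b))
    return out


def as_set(ps):
    return set(zip(ps.a_idx.tolist(), ps.b_idx.tolist()))


def test_unanimous_ordering_is_stable(make_matrix):
    x = np.tile([[0.1], [0.2], [0.3]], (1, 10))
    ps = find_stable_pairs(make_matrix(x), f=0.99)
    assert (0, 1) in as_set(ps) and (0, 2) in as_set(ps) and (1, 2) in as_set(ps)
    assert (1, 0) not in as_set(ps)


def test_nine_of_ten_fails_at_99_percent(make_matrix):
    """ceil(0.99 * 10) = 10, so a single discordant sample disqualifies."""
    x = np.tile([[0.1], [0.2]], (1, 10))
    x[0, 0], x[1, 0] = 0.2, 0.1  # one sample reversed
    ps = find_stable_pairs(make_matrix(x), f=0.99)
    assert as_set(ps) == set()


def test_ties_and_missing_support_neither_direction(make_matrix):
    x = np.tile([[0.1], [0.2]], (1, 10)).astype(float)
    x[0, 0] = 0.2          # tie in sample 0
    x[1, 1] = np.nan       # missing in sample 1
    ps = find_stable_pairs(make_matrix(x), f=0.8)  # need ceil(8) = 8 of 10
    assert as_set(ps) == {(0, 1)}
    ps = find_stable_pairs(make_matrix(x), f=0.9)  # need 9 > 8 supporting
    assert as_set(ps) == set()


def test_matches_exhaustive_oracle_on_random_matrix(make_matrix):
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 1, size=(20, 30))
    m = make_matrix(x)
    for f in (0.7, 0.9, 0.99):
        assert as_set(find_stable_pairs(m, f)) == oracle_pairs(x, f)


def test_blockwise_counting_is_invariant_to_block_sizes(make_matrix):
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, size=(40, 25))
    m = make_matrix(x)
    ref = as_set(find_stable_pairs(m, 0.9))
    assert as_set(find_stable_pairs(m, 0.9, site_block=7, sample_block=4)) == ref


def test_antisymmetry_and_monotonicity_in_f(make_matrix):
    rng = np.random.default_rng(7)
    m = make_matrix(rng.uniform(0, 1, size=(15, 20)))
    prev = None
    for f in (1.0, 0.95, 0.9, 0.8, 0.7, 0.6):
        pairs = as_set(find_stable_pairs(m, f))
        assert all((b, a) not in pairs for a, b in pairs)
        if prev is not None:
            assert prev <= pairs  # raising f never adds pairs
        prev = pairs


def test_f_at_or_below_half_is_rejected(make_matrix):
    m = make_matrix(np.random.default_rng(0).uniform(size=(4, 6)))
    with pytest.raises(ValueError, match="0.5"):
        find_stable_pairs(m, f=0.5)


def binom_tail_oracle(k, s, Pe=Fraction(1, 2)):
    """Direct summation of the cumulative binomial upper tail."""
    return 1 - sum(
        Fraction(comb(k, i)) * Pe**i * (1 - Pe) ** (k - i) for i in range(s)
    )


@pytest.mark.parametrize(
    "k, s, expected",
    [(1, 0, 1.0), (10, 10, 2.0**-10), (2, 2, 0.25)],
)
def test_binomial_tail_closed_forms(k, s, expected):
    assert binomial_tail_p(k, s) == pytest.approx(expected, abs=1e-15)


def test_binomial_tail_large_k_is_finite_and_small():
    p = binomial_tail_p(10**9, 600_000_000)
    assert 0.0 <= p < 1e-300 or p == 0.0


def _pair_set(site_ids, pairs, f=0.99, n=10):
    a = np.array([p[0] for p in pairs], dtype=np.int64)
    b = np.array([p[1] for p in pairs], dtype=np.int64)
    return StablePairSet(site_ids, a, b, f, n)


def test_concordance_counts_shared_and_same_direction():
    ids = ["a", "b", "c", "d"]
    A = _pair_set(ids, [(0, 1), (1, 2), (2, 3)])
    B = _pair_set(ids, [(0, 1), (2, 1), (0, 3)])
    res = concordance(A, B)
    # shared unordered pairs: {a,b} and {b,c}; only {a,b} agrees in direction
    assert res.k == 2 and res.s == 1
    assert res.concordance == pytest.approx(0.5)
    assert res.overlap_fraction == pytest.approx(2 / 3)
    assert res.p_value == pytest.approx(float(binom_tail_oracle(2, 1)), abs=1e-15)


def test_concordance_requires_shared_pairs():
    ids = ["a", "b", "c", "d"]
    A = _pair_set(ids, [(0, 1)])
    B = _pair_set(ids, [(2, 3)])
    with pytest.raises(ValueError, match="no shared pairs"):
        concordance(A, B)


def test_zero_noise_platforms_fully_concordant(make_matrix):
    """Noise-free cohorts give concordance 1 between platform subsets."""
    from rmodm.synthetic import SimConfig, simulate_cohort, split_platforms

    cfg = SimConfig(n_sites=40, n_normals=10, n_tumors=0, n_paired=0,
                    noise_sd=0.0, effect_size=0.0, universal_fraction=0,
                    subtype_fraction=0, seed=5)
    cohort = simulate_cohort(cfg)
    pa, pb, shared = split_platforms(cohort.normals, cfg)
    fa = find_stable_pairs(pa.subset_sites(shared), f=0.99)
    fb = find_stable_pairs(pb.subset_sites(shared), f=0.99)
    res = concordance(fa, fb)
    assert res.concordance == 1.0
    assert res.overlap_fraction == 1.0


def test_pair_set_roundtrip(tmp_path, make_matrix):
    rng = np.random.default_rng(9)
    m = make_matrix(rng.uniform(size=(12, 15)))
    ps = find_stable_pairs(m, 0.9)
    path = tmp_path / "pairs.tsv"
    write_stable_pairs(ps, path)
    back = read_stable_pairs(path, m.site_ids)
    assert as_set(back) == as_set(ps)
    assert back.threshold == ps.threshold and back.n_samples == ps.n_samples


def test_partner_index_matches_pair_set(make_matrix):
    rng = np.random.default_rng(13)
    m = make_matrix(rng.uniform(size=(10, 12)))
    ps = find_stable_pairs(m, 0.8)
    pairs = as_set(ps)
    for c in range(10):
        above = set(ps.partners_above(c).tolist())
        below = set(ps.partners_below(c).tolist())
        assert above == {b for (a, b) in pairs if a == c}
        assert below == {a for (a, b) in pairs if b == c}
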