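"""Mine stable relative methylation orderings and check reproducibility.

Splits the normal pool into two halves on two platform-like probe
subsets, mines each half's stable pair list at the 99% threshold and
compares the lists on the shared probes with the cumulative binomial
concordance test.
"""

from rmodm import SimConfig, concordance, find_stable_pairs, simulate_cohort, \
    split_platforms

cfg = SimConfig(seed=1)
cohort = simulate_cohort(cfg)

pairs = find_stable_pairs(cohort.normals, f=0.99)
print(f"{len(pairs)} site pairs keep one ordering in >= 99% of "
      f"{pairs.n_samples} normal samples "
      f"({len(pairs) / (cfg.n_sites * (cfg.n_sites - 1)):.0%} of ordered pairs)")

pa, pb, shared = split_platforms(cohort.normals, cfg)
half = cohort.normals.n_samples // 2
a = find_stable_pairs(pa.subset_sites(shared).subset_samples(cohort.normals.sample_ids[:half]))
b = find_stable_pairs(pb.subset_sites(shared).subset_samples(cohort.normals.sample_ids[half:]))
res = concordance(a, b)
print(f"shared pairs between the half-cohorts: k={res.k} "
      f"({res.overlap_fraction:.1%} of the shorter list)")
print(f"same-direction fraction s/k = {res.concordance:.4f}, "
      f"binomial p = {res.p_value:.3g}")
# A concordance near 1 with a vanishing p-value is what licenses using
# orderings pooled from many normals as each patient's personal baseline.
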