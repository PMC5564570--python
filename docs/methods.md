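# Methods

## Model and assumptions

The analysis rests on one empirical premise: within a normal tissue
type, the relative methylation ordering (RMO) of most CpG-site pairs —
sign(β(a) − β(b)) inside one sample — is conserved across individuals,
while cancer disrupts many of these orderings. Calling differential
methylation (DM) from *reversed orderings* rather than from deviations
of absolute beta values makes the test self-contained within each
sample: it needs no normalization across samples and no assumption that
a patient's healthy baseline equals the population mean.

For a candidate site c in one cancer sample, partners stably above c
that are observed below it (r_above of n_above) are evidence of
hypermethylation; partners stably below observed above (r_below of
n_below) are evidence of hypomethylation. Under the null — c unchanged,
background orderings intact up to the detection error tolerated by the
stability threshold — both sides reverse at the same small rate, so the
two-sided Fisher exact test on [[r_above, n_above−r_above],
[r_below, n_below−r_below]] is calibrated. A genuinely shifted site
concentrates reversals on one side. Note the structural limit: the test
contrasts the two partner margins, so a site with stable partners on
only one side of itself (a site pinned at an extreme of the methylation
scale) can never reach significance, whatever happens to it.

Candidates are pre-filtered to sites that are population-level DM in two
independent cohorts with concordant direction; this anchors individual
calls to reproducible cancer-associated sites and shrinks the per-sample
multiplicity burden.

## Parameters

| parameter | default | meaning |
|---|---|---|
| stability f | 0.99 | pair stable when one ordering holds in ≥ ⌈f·N⌉ of N normals; realizes "at least 99%", tolerating a 1% detection error |
| Pe | 0.5 | chance same-direction probability in the pair-list concordance binomial |
| population FDR | 0.01 | BH cut per cohort for the t-test filter |
| individual FDR | 0.01 | BH cut across tested candidates within one sample |
| min_partners | 5 | below this many usable partners a site is untested (reported `tested=False`, never a negative call) |
| refine_iters | 1 | passes that re-count with DM-called partners excluded from every site's background |
| delta_min | 0 | minimum |β_tumor − β_adjacent| for a gold direction; sub-threshold differences count any call as FP (strictest reading) |
| universal threshold | 0.95 | gene class boundary, strict: frequency > 0.95 |
| hetero interval | [0.20, 0.80] | closed band for heterogeneous genes |
| pathway FDR | 0.1 | BH cut across pathways within one (sample, direction) |

Choices where conventions diverge: Welch's t-test (unequal variances;
pooled-variance optional via `equal_var`); ⌈f·N⌉ rather than ⌊f·N⌋;
ties and missing values in stability counting support neither direction
while N stays the full sample count (absolute error allowance); in
reversal counting a tied partner is a non-reversal that stays in the
denominator, while a missing partner leaves both numerator and
denominator; BH families are per cohort (population), per sample
(individual calls) and per sample × direction (pathways), because those
are the units at which claims are made. The Fisher two-sidedness is the
standard exact convention: total probability of fixed-margin tables no
more probable than the observed one, computed by integer enumeration
(exact including ties). Gene-level inconsistency (both directions in one
promoter) is excluded per sample, not globally, and the inconsistent
fraction is reported; frequency denominators are all cohort samples.
The enrichment universe defaults to the genes covered by the pathway
collection, configurable where a study prefers all annotated genes.

## The synthetic cohort

The generator reproduces the structure the method assumes, with full
ground truth. Per site, a baseline beta μ_i is drawn uniformly from
`baseline_range` (default 0.05–0.95); a sample's value is
inverse-logit(logit(μ_i) + ε), ε ~ N(0, noise_sd²), clipped to
[1e-6, 1−1e-6]. Planted events add ±`effect_size` on the logit scale
before noise. Defaults: 300 sites, 40 normals, 30 tumors (20 paired
with event-free adjacent normals), noise_sd 0.3, effect 2.0 logits —
a clear-signal operating point at which per-pair noise (√2·0.3 logits)
is small against typical baseline gaps, as in a homogeneous-tissue
array study.

Site classes: 10% of sites are *universal* (each planted in ≥ ⌈0.95·T⌉
of T tumors), 20% *subtype* (a uniform-size subset within
[⌈0.20·T⌉, ⌊0.80·T⌋]), the rest null. Direction (hyper/hypo, p = 0.5)
is assigned per gene block — annotations group `sites_per_gene`
consecutive sites per gene and `genes_per_pathway` consecutive genes
per pathway — so planted genes are internally consistent and the first
pathway collects exactly the universal genes. Planted sites draw their
baselines from the central 40% of the baseline range: intermediate
methylation is both where array differential signal concentrates and
the regime in which a site has stable partners on both sides, i.e. both
margins of the Fisher contrast are populated (see the structural limit
above). Null sites span the whole range. One integer seed feeds a root
`SeedSequence`; per-component child streams (directions, baselines,
event placement, noise) make outputs reproducible bit-for-bit.

What the generator does **not** emulate: Infinium I/II probe-chemistry
bias, batch and lab effects, cell-type composition, spatial correlation
of neighboring CpGs beyond the shared-gene blocks, and realistic
effect-size distributions. Passing recovery tests therefore demonstrates
the machinery is correct under the stated generative model, not that
real-tissue precision will match the synthetic numbers.

## Problem sizes and numerics

The default study conditions (300 sites, 40+30 samples) keep a full
pipeline run under a second while leaving ~26k stable pairs and ~90
planted sites — enough that every stage's statistics are exercised far
from degenerate regimes. Stable-pair counting is blockwise over sites
and samples, so memory stays at one `site_block × n_sites` int panel
and platform-scale universes (~26k sites) remain feasible. The binomial
concordance tail uses the survival function (safe for k ~ 10⁹ pairs);
the Fisher p is an exact rational sum evaluated with Python integers
(one rounding at the final division); hypergeometric tails come from
`scipy.stats.hypergeom.sf`. Degenerate inputs are defined, not special-
cased away: a Fisher table with an empty margin has a single reachable
outcome and p = 1; a site missing its value in a sample is untested; an
empty tumor matrix yields an empty call table with a warning.

Pipeline runs are deterministic: no timestamps in outputs, JSON keys
sorted, so a rerun with the same config and seed is byte-identical —
the property the determinism test asserts.

## Known limitations

- Calls inherit the candidate filter: a site disrupted in one patient
  but not population-level DM is invisible by design.
- The reversal test needs partners on both sides; extreme-methylation
  sites are structurally untestable (reported untested, not negative).
- Precision against adjacent normals assumes the adjacent tissue
  approximates the patient's pre-disease state; field effects in real
  adjacent tissue would depress measured precision without the calls
  being wrong.
- The refinement pass approximates an iterative background-cleaning
  idea with a fixed small number of passes; it changes little at the
  default operating point (the null fixed-point test pins the no-op
  case).
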