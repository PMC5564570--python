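"""Synthetic methylation cohorts with known ground truth.

The generator emulates the statistical structure that rank-based
individualized calling relies on:

* a pool of normal samples whose between-site beta orderings are highly
  conserved (per-site baseline + small logit-scale noise),
* tumor samples carrying planted hyper/hypomethylation events -- a fixed
  logit shift at chosen (site, sample) positions -- at controlled
  per-site frequencies: *universal* sites disrupted in >= 95% of tumors,
  *subtype* sites in a 20-80% subset, the rest untouched,
* paired tumor / adjacent-normal samples (the adjacent normal never
  carries planted events),
* two platform-like site subsets with a shared core, and
* block-structured gene and pathway annotations so that planted events
  propagate cleanly to gene and pathway level.

Planted sites draw their baselines from the central band of the baseline
range (intermediate normal methylation), so each carries stable partners
both above and below itself -- the two margins of the reversal test.  A
site pinned at an extreme of the methylation scale has partners on one
side only and its disruption is structurally invisible to an
ordering-based test; intermediate-methylation CpGs are also where array
studies find their differential signal.  Null sites span the full range.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .matrix import BetaMatrix, write_annotation, write_beta_matrix, write_gmt
from .population import HYPER, HYPO

BETA_CLIP = 1e-6  # keep logits finite

UNIVERSAL = "universal"
SUBTYPE = "subtype"
NULL = "null"


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic methylation cohort.

    Defaults give a small cohort (300 sites, 40 normals, 30 tumors of
    which 20 are paired with adjacent normals) with a 2-logit planted
    shift against 0.3-logit noise -- strong, clean signal of the kind a
    focused array study of a homogeneous tissue would show.
    """

    n_sites: int = 300
    n_normals: int = 40
    n_tumors: int = 30
    n_paired: int = 20
    baseline_range: tuple[float, float] = (0.05, 0.95)
    noise_sd: float = 0.3          # sd of logit-scale noise
    universal_fraction: float = 0.1
    subtype_fraction: float = 0.2
    effect_size: float = 2.0       # logit-scale shift of a planted event
    hyper_prob: float = 0.5        # P(a planted gene is hypermethylated)
    platform_overlap_fraction: float = 0.8
    genes_per_pathway: int = 10
    sites_per_gene: int = 3
    seed: int = 0

    # class frequency bands (fractions of tumors carrying the event)
    universal_min_freq: float = 0.95
    subtype_freq: tuple[float, float] = (0.20, 0.80)

    def validate(self) -> None:
        def check(cond: bool, fieldname: str, msg: str) -> None:
            if not cond:
                raise SimConfigError(f"{fieldname}: {msg}")

        check(self.n_sites >= 1, "n_sites", "must be >= 1")
        check(self.n_normals >= 0, "n_normals", "must be >= 0")
        check(self.n_tumors >= 0, "n_tumors", "must be >= 0")
        check(0 <= self.n_paired <= self.n_tumors, "n_paired",
              "must be between 0 and n_tumors")
        lo, hi = self.baseline_range
        check(0 < lo < hi < 1, "baseline_range", "needs 0 < low < high < 1")
        check(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        check(self.effect_size >= 0, "effect_size", "must be non-negative")
        for name in ("universal_fraction", "subtype_fraction", "hyper_prob",
                     "platform_overlap_fraction"):
            check(0 <= getattr(self, name) <= 1, name, "must be in [0, 1]")
        check(self.universal_fraction + self.subtype_fraction <= 1,
              "universal_fraction", "universal_fraction + subtype_fraction "
              "must not exceed 1")
        check(self.genes_per_pathway >= 1, "genes_per_pathway", "must be >= 1")
        check(self.sites_per_gene >= 1, "sites_per_gene", "must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-event table and per-site class labels."""

    events: pd.DataFrame        # site_id, sample_id, direction, shift
    site_class: pd.Series       # site_id -> universal | subtype | null
    site_direction: pd.Series   # site_id -> hyper | hypo (planted sites only)

    def event_frequency(self, n_tumors: int) -> pd.Series:
        """Fraction of tumors carrying an event, per planted site."""
        return self.events.groupby("site_id").size() / n_tumors


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces."""

    config: SimConfig
    normals: BetaMatrix
    tumors: BetaMatrix
    adjacents: BetaMatrix
    pairing: dict[str, str]     # tumor sample id -> adjacent normal id
    truth: SyntheticTruth
    annotation: pd.Series       # probe_id -> gene_symbol
    pathways: dict[str, list[str]]


def _site_ids(n: int) -> list[str]:
    return [f"cg{i:06d}" for i in range(n)]


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one full synthetic cohort under ``config`` (deterministic per seed)."""
    config.validate()
    c = config
    ss = np.random.SeedSequence(c.seed)
    (rng_dir, rng_base, rng_events, rng_noise) = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n = c.n_sites
    site_ids = _site_ids(n)
    n_uni = round(c.universal_fraction * n)
    n_sub = round(c.subtype_fraction * n)
    classes = np.array([UNIVERSAL] * n_uni + [SUBTYPE] * n_sub
                       + [NULL] * (n - n_uni - n_sub), dtype=object)

    # gene-block structure: sites_per_gene consecutive sites per gene
    n_genes = math.ceil(n / c.sites_per_gene)
    gene_of_site = np.arange(n) // c.sites_per_gene
    gene_ids = [f"GENE{g:04d}" for g in range(n_genes)]
    annotation = pd.Series([gene_ids[g] for g in gene_of_site],
                           index=site_ids, name="gene_symbol")

    # one planted direction per gene so promoter calls stay consistent
    gene_dir = np.where(rng_dir.random(n_genes) < c.hyper_prob, HYPER, HYPO)
    site_dir = gene_dir[gene_of_site]

    # baselines: null sites span the range; planted sites sit in the central
    # band so stable partners exist on both sides of them (both margins of
    # the reversal test are populated)
    lo, hi = c.baseline_range
    band_lo = lo + 0.3 * (hi - lo)
    band_hi = lo + 0.7 * (hi - lo)
    mu = rng_base.uniform(lo, hi, size=n)
    planted = classes != NULL
    draw = rng_base.uniform(0, 1, size=n)
    mu[planted] = band_lo + (band_hi - band_lo) * draw[planted]
    base_logit = logit(mu)

    tumor_ids = [f"T{i:03d}" for i in range(c.n_tumors)]
    normal_ids = [f"N{i:03d}" for i in range(c.n_normals)]
    adj_ids = [f"A{i:03d}" for i in range(c.n_paired)]
    pairing = dict(zip(tumor_ids[: c.n_paired], adj_ids))

    # planted events: per planted site, a random tumor subset in the class band
    shift = np.zeros((n, c.n_tumors))
    ev_rows = []
    if c.n_tumors:
        uni_lo = math.ceil(c.universal_min_freq * c.n_tumors)
        sub_lo = math.ceil(c.subtype_freq[0] * c.n_tumors)
        sub_hi = math.floor(c.subtype_freq[1] * c.n_tumors)
        for i in np.flatnonzero(planted):
            if classes[i] == UNIVERSAL:
                k = int(rng_events.integers(uni_lo, c.n_tumors + 1))
            else:
                k = int(rng_events.integers(sub_lo, max(sub_lo, sub_hi) + 1))
            hit = rng_events.choice(c.n_tumors, size=k, replace=False)
            sgn = 1.0 if site_dir[i] == HYPER else -1.0
            shift[i, hit] = sgn * c.effect_size
            for j in sorted(hit):
                ev_rows.append((site_ids[i], tumor_ids[j], site_dir[i],
                                sgn * c.effect_size))
    events = pd.DataFrame(ev_rows,
                          columns=["site_id", "sample_id", "direction", "shift"])

    def draw_matrix(n_cols: int, offset: np.ndarray | float) -> np.ndarray:
        eps = rng_noise.normal(0.0, c.noise_sd, size=(n, n_cols)) if n_cols else \
            np.zeros((n, 0))
        betas = expit(base_logit[:, None] + offset + eps)
        return np.clip(betas, BETA_CLIP, 1 - BETA_CLIP)

    normals_arr = draw_matrix(c.n_normals, 0.0)
    tumors_arr = draw_matrix(c.n_tumors, shift)
    adj_arr = draw_matrix(c.n_paired, 0.0)

    def bm(arr: np.ndarray, cols: list[str], group: str) -> BetaMatrix:
        return BetaMatrix(
            pd.DataFrame(arr, index=site_ids, columns=cols),
            pd.Series(group, index=cols, dtype=object),
        )

    truth = SyntheticTruth(
        events=events,
        site_class=pd.Series(classes, index=site_ids, name="site_class"),
        site_direction=pd.Series(
            np.where(planted, site_dir, ""), index=site_ids, name="direction"
        ),
    )
    pathways = {
        f"PW{p:03d}": gene_ids[p * c.genes_per_pathway:(p + 1) * c.genes_per_pathway]
        for p in range(math.ceil(n_genes / c.genes_per_pathway))
    }
    return SyntheticCohort(
        config=c,
        normals=bm(normals_arr, normal_ids, "normal"),
        tumors=bm(tumors_arr, tumor_ids, "tumor"),
        adjacents=bm(adj_arr, adj_ids, "adjacent_normal"),
        pairing=pairing,
        truth=truth,
        annotation=annotation,
        pathways=pathways,
    )


def split_platforms(matrix: BetaMatrix, config: SimConfig
                    ) -> tuple[BetaMatrix, BetaMatrix, list[str]]:
    """Split sites into two platform-like subsets with a shared core.

    The shared core has ``round(platform_overlap_fraction * n_sites)``
    sites; the remaining sites alternate between the two platforms, so
    the union always covers every site.
    """
    f = config.platform_overlap_fraction
    if not 0 <= f <= 1:
        raise SimConfigError("platform_overlap_fraction: must be in [0, 1]")
    sites = matrix.site_ids
    n_shared = round(f * len(sites))
    shared = sites[:n_shared]
    rest = sites[n_shared:]
    only_a = rest[0::2]
    only_b = rest[1::2]
    a = matrix.subset_sites(shared + only_a)
    b = matrix.subset_sites(shared + only_b)
    return a, b, shared


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write every cohort artifact as plain-text files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(cohort.normals, out / "normals.tsv")
    write_beta_matrix(cohort.tumors, out / "tumors.tsv")
    write_beta_matrix(cohort.adjacents, out / "adjacent_normals.tsv")
    pd.DataFrame(
        {"tumor_id": list(cohort.pairing), "adjacent_id": list(cohort.pairing.values())}
    ).to_csv(out / "pairing.tsv", sep="\t", index=False)
    cohort.truth.events.to_csv(out / "truth_events.tsv", sep="\t", index=False)
    pd.DataFrame({
        "site_id": cohort.truth.site_class.index,
        "site_class": cohort.truth.site_class.values,
        "direction": cohort.truth.site_direction.values,
    }).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    write_annotation(cohort.annotation, out / "annotation.tsv")
    write_gmt(cohort.pathways, out / "pathways.gmt", description="synthetic")


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["baseline_range"] = list(d["baseline_range"])
    d["subtype_freq"] = list(d["subtype_freq"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "baseline_range" in d:
        d["baseline_range"] = tuple(d["baseline_range"])
    if "subtype_freq" in d:
        d["subtype_freq"] = tuple(d["subtype_freq"])
    return SimConfig(**d)
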