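"""Per-sample hypergeometric pathway enrichment of DM gene sets.

For each sample, the hyper- and hypomethylated gene sets are tested
separately against every pathway with an upper-tail hypergeometric test
(k or more of the n DM genes falling in a K-gene pathway within an
N-gene universe), BH-adjusted across pathways within each
(sample, direction) family.  The cross-sample *significance frequency*
of a pathway -- the fraction of samples in which it is enriched at the
FDR cut -- summarizes how universally a pathway is disrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .aggregate import GeneDMMatrix
from .population import HYPER, HYPO, bh_adjust

log = logging.getLogger(__name__)


@dataclass
class HypergeomResult:
    k: int      # DM genes in the pathway
    K: int      # pathway size within the universe
    n: int      # DM set size within the universe
    N: int      # universe size
    p: float    # P(overlap >= k)


def hypergeom_enrich(
    dm_genes: Iterable[str],
    pathway: Iterable[str],
    universe: Iterable[str],
) -> HypergeomResult:
    """Upper-tail hypergeometric overlap test within a fixed gene universe.

    Both gene sets are intersected with the universe first; the pathway
    must be contained in it.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    pw = set(pathway)
    if not pw <= uni:
        raise ValueError("pathway genes must be a subset of the universe")
    dm = set(dm_genes) & uni
    if not dm:
        raise ValueError("empty DM gene set after restriction to the universe")
    k = len(dm & pw)
    K, n, N = len(pw), len(dm), len(uni)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return HypergeomResult(k=k, K=K, n=n, N=N, p=min(p, 1.0))


def enrich_cohort(
    genes: GeneDMMatrix,
    pathways: Mapping[str, list[str]],
    fdr: float = 0.1,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-sample, per-direction enrichment of every pathway.

    The default universe is the union of pathway genes (restricted
    further if ``universe`` is given).  Samples with an empty DM set in
    a direction leave all pathways untested for that (sample, direction).
    Returns a long frame: sample_id, pathway_id, direction, k, K, n, N,
    p, q, significant.
    """
    if not pathways:
        raise ValueError("pathway collection is empty")
    uni = set().union(*pathways.values())
    if universe is not None:
        uni &= set(universe)
    if not uni:
        raise ValueError("empty enrichment universe")
    states = genes.states
    rows = []
    sample_ids = list(pd.unique(states["sample_id"])) if len(states) else []
    for sid in sample_ids:
        mine = states[states["sample_id"] == sid]
        for direction in (HYPER, HYPO):
            dm = set(mine.loc[mine["state"] == direction, "gene"]) & uni
            if not dm:
                continue
            block = []
            for pw_id, pw_genes in pathways.items():
                pw = set(pw_genes) & uni
                res = HypergeomResult(
                    k=len(dm & pw), K=len(pw), n=len(dm), N=len(uni),
                    p=float(stats.hypergeom.sf(len(dm & pw) - 1, len(uni),
                                               len(pw), len(dm))),
                )
                block.append((sid, pw_id, direction, res.k, res.K, res.n,
                              res.N, min(res.p, 1.0)))
            sub = pd.DataFrame(block, columns=["sample_id", "pathway_id",
                                               "direction", "k", "K", "n",
                                               "N", "p"])
            sub["q"] = bh_adjust(sub["p"].to_numpy())
            sub["significant"] = sub["q"] < fdr
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["sample_id", "pathway_id", "direction",
                                     "k", "K", "n", "N", "p", "q",
                                     "significant"])
    return pd.concat(rows, ignore_index=True)


def significance_frequency(table: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Fraction of samples in which each (pathway, direction) is significant."""
    if table.empty:
        return pd.DataFrame(columns=["pathway_id", "direction", "frequency"])
    freq = (
        table.groupby(["pathway_id", "direction"])["significant"]
        .sum()
        .div(n_samples)
        .rename("frequency")
        .reset_index()
    )
    return freq
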