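"""Mining highly stable within-sample relative methylation orderings (RMOs).

For a pair of CpG sites (a, b), the RMO records which site has the higher
beta value inside one sample.  Across a pool of normal samples many such
orderings are near-invariant; a directed pair (a, b) is *stable* at
threshold f when ``beta(a) < beta(b)`` holds in at least ``ceil(f * N)``
of the N pooled normals.  Ties and missing values support neither
direction but still count in N, so the rule reads as an absolute
"at most (1-f) exceptions" allowance.

Two stable-pair lists (e.g. from different array platforms) are compared
by their concordance s/k over the k pairs stable in both, with an
upper-tail cumulative binomial p-value for observing s same-direction
pairs by chance (chance agreement probability Pe, default 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import BetaMatrix


@dataclass
class StablePairSet:
    """Directed stable pairs over a fixed site universe.

    ``a_idx[i], b_idx[i]`` index into ``site_ids`` and encode the ordering
    ``beta(site_ids[a_idx[i]]) < beta(site_ids[b_idx[i]])``.
    """

    site_ids: list[str]
    a_idx: np.ndarray
    b_idx: np.ndarray
    threshold: float
    n_samples: int
    _above: dict[int, np.ndarray] | None = field(default=None, repr=False)
    _below: dict[int, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.a_idx = np.asarray(self.a_idx, dtype=np.int64)
        self.b_idx = np.asarray(self.b_idx, dtype=np.int64)
        if self.a_idx.shape != self.b_idx.shape:
            raise ValueError("a_idx and b_idx must have equal length")

    def __len__(self) -> int:
        return len(self.a_idx)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def _build_index(self) -> None:
        above: dict[int, list[int]] = {}
        below: dict[int, list[int]] = {}
        for a, b in zip(self.a_idx.tolist(), self.b_idx.tolist()):
            above.setdefault(a, []).append(b)
            below.setdefault(b, []).append(a)
        self._above = {k: np.array(v, dtype=np.int64) for k, v in above.items()}
        self._below = {k: np.array(v, dtype=np.int64) for k, v in below.items()}

    def partners_above(self, site: int) -> np.ndarray:
        """Site indexes stably *above* ``site`` (pairs (site, b))."""
        if self._above is None:
            self._build_index()
        return self._above.get(site, np.empty(0, dtype=np.int64))

    def partners_below(self, site: int) -> np.ndarray:
        """Site indexes stably *below* ``site`` (pairs (a, site))."""
        if self._below is None:
            self._build_index()
        return self._below.get(site, np.empty(0, dtype=np.int64))

    def pair_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.site_ids, dtype=object)
        return pd.DataFrame({"site_a": ids[self.a_idx], "site_b": ids[self.b_idx]})


@dataclass
class ConcordanceResult:
    """Agreement between two stable-pair lists over shared pairs."""

    k: int                    # shared (unordered) stable pairs
    s: int                    # shared pairs with the same direction
    concordance: float        # s / k
    Pe: float                 # chance same-direction probability
    p_value: float            # upper-tail cumulative binomial P(X >= s)
    overlap_fraction: float   # k / size of the smaller list


def stability_threshold(f: float, n_samples: int) -> int:
    """Minimum supporting-sample count realizing "at least f of N"."""
    return math.ceil(f * n_samples)


def find_stable_pairs(
    normals: BetaMatrix,
    f: float = 0.99,
    *,
    site_block: int = 256,
    sample_block: int = 64,
) -> StablePairSet:
    """Mine directed stable pairs from pooled normal samples.

    A pair (a, b) is emitted when ``beta(a) < beta(b)`` strictly in at
    least ``ceil(f * N)`` of the N samples; tied or missing cells support
    neither direction.  Counting is blockwise over sites and samples so
    the full O(n^2) pair grid is never materialized at once (only one
    ``site_block x n`` count panel lives in memory), which keeps platform-
    scale inputs (~26k sites) tractable.
    """
    if not 0.5 < f <= 1.0:
        raise ValueError(
            f"stability threshold f must be in (0.5, 1], got {f}; "
            "at f <= 0.5 both directions of a pair could qualify"
        )
    if normals.n_samples < 2:
        raise ValueError("need at least two normal samples to mine stable pairs")
    x = normals.to_numpy()
    n, N = x.shape
    need = stability_threshold(f, N)
    a_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    for start in range(0, n, site_block):
        stop = min(start + site_block, n)
        block = x[start:stop]
        counts = np.zeros((stop - start, n), dtype=np.int32)
        for s0 in range(0, N, sample_block):
            s1 = min(s0 + sample_block, N)
            with np.errstate(invalid="ignore"):
                cmp = block[:, None, s0:s1] < x[None, :, s0:s1]  # NaN -> False
            counts += cmp.sum(axis=2, dtype=np.int32)
        rows, cols = np.nonzero(counts >= need)
        a_parts.append(rows + start)
        b_parts.append(cols)
    a_idx = np.concatenate(a_parts) if a_parts else np.empty(0, dtype=np.int64)
    b_idx = np.concatenate(b_parts) if b_parts else np.empty(0, dtype=np.int64)
    return StablePairSet(list(normals.site_ids), a_idx, b_idx, f, N)


def binomial_tail_p(k: int, s: int, Pe: float = 0.5) -> float:
    """Upper-tail cumulative binomial ``1 - sum_{i<s} C(k,i) Pe^i (1-Pe)^(k-i)``.

    Computed through the binomial survival function, which stays accurate
    for k up to the billions of pairs real platforms produce.
    """
    if s == 0:
        return 1.0
    return float(stats.binom.sf(s - 1, k, Pe))


def concordance(listA: StablePairSet, listB: StablePairSet,
                Pe: float = 0.5) -> ConcordanceResult:
    """Compare two stable-pair lists: shared pairs, direction agreement, p.

    A pair is *shared* when the unordered site pair is stable in both lists
    (in either direction); ``s`` counts shared pairs whose direction also
    agrees.  Raises if no pairs are shared (k = 0 leaves the concordance
    undefined).
    """
    if len(listA) == 0 or len(listB) == 0:
        raise ValueError("both stable-pair lists must be nonempty")

    def directed(ps: StablePairSet) -> dict[tuple[str, str], bool]:
        ids = np.asarray(ps.site_ids, dtype=object)
        out: dict[tuple[str, str], bool] = {}
        for a, b in zip(ids[ps.a_idx], ids[ps.b_idx]):
            if a <= b:
                out[(a, b)] = True      # canonical order, forward direction
            else:
                out[(b, a)] = False
        return out

    da, db = directed(listA), directed(listB)
    shared = da.keys() & db.keys()
    k = len(shared)
    if k == 0:
        raise ValueError("no shared pairs between the two lists (k = 0)")
    s = sum(1 for key in shared if da[key] == db[key])
    return ConcordanceResult(
        k=k,
        s=s,
        concordance=s / k,
        Pe=Pe,
        p_value=binomial_tail_p(k, s, Pe),
        overlap_fraction=k / min(len(listA), len(listB)),
    )


def write_stable_pairs(pairs: StablePairSet, path: str | Path) -> None:
    """Serialize the pair list as TSV plus a small metadata sidecar."""
    path = Path(path)
    pairs.pair_frame().to_csv(path, sep="\t", index=False)
    meta = path.with_suffix(path.suffix + ".meta")
    meta.write_text(
        f"threshold\t{pairs.threshold}\nn_samples\t{pairs.n_samples}\n"
        f"n_pairs\t{len(pairs)}\n"
    )


def read_stable_pairs(path: str | Path, site_ids: list[str],
                      threshold: float | None = None,
                      n_samples: int | None = None) -> StablePairSet:
    """Load a serialized pair list; metadata defaults to the sidecar file."""
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta")
    if (threshold is None or n_samples is None) and meta_path.exists():
        meta = dict(
            line.split("\t") for line in meta_path.read_text().splitlines() if line
        )
        threshold = float(meta["threshold"]) if threshold is None else threshold
        n_samples = int(meta["n_samples"]) if n_samples is None else n_samples
    if threshold is None or n_samples is None:
        raise ValueError(f"no metadata sidecar at {meta_path}; "
                         "pass threshold and n_samples explicitly")
    df = pd.read_csv(path, sep="\t", dtype=str)
    pos = {sid: i for i, sid in enumerate(site_ids)}
    a_idx = np.array([pos[s] for s in df["site_a"]], dtype=np.int64)
    b_idx = np.array([pos[s] for s in df["site_b"]], dtype=np.int64)
    return StablePairSet(list(site_ids), a_idx, b_idx, threshold, n_samples)
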