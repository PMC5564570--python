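"""Methylation beta-value matrices and the plain-text formats around them.

The central container is :class:`BetaMatrix`, a CpG-site x sample grid of
beta values in [0, 1] (missing cells allowed) with an optional group label
per sample (``normal`` / ``tumor`` / ``adjacent_normal``).  On disk the
matrix is a TSV with a ``probe_id`` first column, sample ids as the header
row and ``NA`` for missing cells.  Probe-to-gene promoter annotations are a
two-column TSV; pathway gene sets use the standard GMT dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUP_LABELS = ("normal", "tumor", "adjacent_normal")

NA_REP = "NA"


class BetaMatrixError(ValueError):
    """Raised for malformed beta matrices or matrix files."""


@dataclass
class BetaMatrix:
    """CpG-site x sample matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame indexed by CpG site id, columns are sample ids, cells are
        beta values in [0, 1] or NaN for missing.
    groups
        Optional per-sample group label, aligned with ``values.columns``.
    """

    values: pd.DataFrame
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate site ids: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise BetaMatrixError(
                f"beta value out of [0, 1] at site {v.index[i]!r}, "
                f"sample {v.columns[j]!r}: {arr[i, j]}"
            )
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(v.columns)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_sites(self, site_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(site_ids)], self.groups)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        g = self.groups[list(sample_ids)] if self.groups is not None else None
        return BetaMatrix(self.values[list(sample_ids)], g)

    def equals(self, other: "BetaMatrix") -> bool:
        return self.values.equals(other.values)


def read_beta_matrix(
    path: str | Path, groups: str | Mapping[str, str] | None = None
) -> BetaMatrix:
    """Read a beta-value TSV (``probe_id`` column + one column per sample).

    ``groups`` may be a single label applied to every sample or a mapping
    from sample id to label.  Cells equal to ``NA`` become missing.
    Out-of-range values, duplicate ids and ragged rows raise
    :class:`BetaMatrixError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False,
            dtype=str,
        )
    except pd.errors.ParserError as exc:
        raise BetaMatrixError(f"{path}: malformed TSV: {exc}") from exc
    if df.index.name != "probe_id":
        raise BetaMatrixError(f"{path}: first column must be 'probe_id'")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise BetaMatrixError(f"{path}: non-numeric beta value: {exc}") from exc
    arr = values.to_numpy()
    bad = np.argwhere((arr < 0) | (arr > 1))
    if len(bad):
        i, j = bad[0]
        # +2: one for the header line, one for 1-based numbering
        raise BetaMatrixError(
            f"{path}, line {i + 2}: beta value {arr[i, j]} for site "
            f"{values.index[i]!r} outside [0, 1]"
        )
    if values.index.has_duplicates:
        dup_site = values.index[values.index.duplicated()][0]
        line = int(np.argwhere(values.index == dup_site)[-1][0]) + 2
        raise BetaMatrixError(f"{path}, line {line}: duplicate site id {dup_site!r}")
    if isinstance(groups, str):
        g = pd.Series(groups, index=values.columns)
    elif groups is not None:
        g = pd.Series({s: groups[s] for s in values.columns})
    else:
        g = None
    return BetaMatrix(values, g)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write a :class:`BetaMatrix` as TSV (round-trips with the reader)."""
    matrix.values.to_csv(Path(path), sep="\t", na_rep=NA_REP, index_label="probe_id")


def read_annotation(path: str | Path) -> pd.Series:
    """Read a probe -> gene promoter annotation TSV.

    Columns ``probe_id`` and ``gene_symbol``.  If a probe appears more than
    once, the first listed gene wins and a warning is logged.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = {"probe_id", "gene_symbol"} - set(df.columns)
    if missing:
        raise BetaMatrixError(f"{path}: missing annotation columns {sorted(missing)}")
    n_dup = int(df["probe_id"].duplicated().sum())
    if n_dup:
        log.warning("%s: %d duplicate probe annotations; keeping first gene", path, n_dup)
        df = df.drop_duplicates("probe_id", keep="first")
    return pd.Series(df["gene_symbol"].values, index=df["probe_id"].values, name="gene_symbol")


def write_annotation(annotation: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": annotation.index, "gene_symbol": annotation.values}
    ).to_csv(Path(path), sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read pathway gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BetaMatrixError(f"{path}, line {lineno}: GMT rows need name, "
                                  "description and at least one gene")
        name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise BetaMatrixError(f"{path}, line {lineno}: duplicate set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
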