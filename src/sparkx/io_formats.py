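"""Input/output containers and data-preparation filters.

Counts are held genes x locations in compressed-sparse-row form so that a
single gene's non-zero entries can be sliced in O(nnz of that gene).
Coordinates and covariates are joined to counts by location id; order
differences are resolved by id and mismatched id sets raise, so silent
misregistration of beads/spots is impossible.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "Coordinates",
    "CovariateTable",
    "read_counts",
    "write_counts",
    "read_coordinates",
    "filter_genes",
    "filter_locations",
    "encode_covariates",
    "align",
    "write_results",
    "MITO_PATTERN",
]

#: default mitochondrial gene-name filter (case-insensitive prefix "mt-")
MITO_PATTERN = "^mt-"


class FormatError(ValueError):
    """Malformed input file."""


class AlignmentError(ValueError):
    """Ids or dimensions of paired inputs do not match."""


@dataclass
class CountMatrix:
    """Sparse genes x locations matrix of non-negative integer counts."""

    values: sp.csr_matrix
    gene_ids: list[str]
    location_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.location_ids = [str(s) for s in self.location_ids]
        p, n = self.values.shape
        if p != len(self.gene_ids) or n != len(self.location_ids):
            raise AlignmentError(
                f"count matrix is {p}x{n} but got {len(self.gene_ids)} gene ids "
                f"and {len(self.location_ids)} location ids"
            )
        if len(set(self.gene_ids)) != p:
            raise AlignmentError("gene ids are not unique")
        if len(set(self.location_ids)) != n:
            raise AlignmentError("location ids are not unique")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise FormatError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_locations(self) -> int:
        return self.values.shape[1]

    def gene_vector(self, i: int) -> np.ndarray:
        """Dense count vector of gene ``i`` over all locations."""
        return np.asarray(self.values[i].todense()).ravel()

    @classmethod
    def from_anndata(cls, adata) -> "CountMatrix":
        """Build from an AnnData (obs = locations, var = genes); transposes to genes x locations."""
        mat = sp.csr_matrix(adata.X.T)
        return cls(mat, list(adata.var_names), list(adata.obs_names))


@dataclass
class Coordinates:
    """n x d spatial positions with location ids aligned to a CountMatrix."""

    positions: np.ndarray
    location_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.location_ids = [str(s) for s in self.location_ids]
        n, d = self.positions.shape
        if d not in (2, 3):
            raise FormatError(f"coordinates must be 2- or 3-dimensional, got d={d}")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("coordinates contain non-finite values")
        if n != len(self.location_ids):
            raise AlignmentError("coordinate rows do not match location ids")
        if len(set(self.location_ids)) != n:
            raise AlignmentError("location ids are not unique")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]


@dataclass
class CovariateTable:
    """Raw per-location covariates: numeric and/or categorical columns."""

    table: pd.DataFrame
    location_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.location_ids:
            self.location_ids = [str(i) for i in self.table.index]
        if self.table.isna().any().any():
            raise FormatError("covariate table contains missing values")


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a genes x locations count matrix.

    ``mtx`` expects ``<stem>.mtx`` plus sibling ``<stem>.genes.txt`` and
    ``<stem>.locations.txt`` id files (one id per line). ``delimited`` expects
    a TSV/CSV with gene ids in the first column and location ids in the header.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "delimited"
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy's message varies
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        genes = _read_ids(path.with_suffix("").with_suffix(".genes.txt"))
        locs = _read_ids(path.with_suffix("").with_suffix(".locations.txt"))
        mat = sp.csr_matrix(mat)
        if mat.shape != (len(genes), len(locs)):
            raise AlignmentError(
                f"matrix is {mat.shape} but id files give "
                f"({len(genes)}, {len(locs)})"
            )
        return CountMatrix(mat, genes, locs)
    if format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        vals = df.to_numpy()
        if np.any(vals < 0):
            raise FormatError("counts must be non-negative")
        return CountMatrix(sp.csr_matrix(vals), list(df.index), list(df.columns))
    raise ValueError(f"unknown format {format!r}")


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing id file {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(m: CountMatrix, path: str | Path) -> None:
    """Write counts as Matrix Market plus gene/location id files."""
    path = Path(path)
    if path.suffix != ".mtx":
        path = path.with_suffix(".mtx")
    scipy.io.mmwrite(str(path), sp.coo_matrix(m.values), field="integer")
    path.with_suffix("").with_suffix(".genes.txt").write_text(
        "\n".join(m.gene_ids) + "\n"
    )
    path.with_suffix("").with_suffix(".locations.txt").write_text(
        "\n".join(m.location_ids) + "\n"
    )


def read_coordinates(path: str | Path) -> Coordinates:
    """Read a delimited file with a location-id column followed by 2 or 3 coordinate columns."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] not in (2, 3):
        raise FormatError(
            f"expected 2 or 3 coordinate columns, got {df.shape[1]}"
        )
    return Coordinates(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_coordinates(c: Coordinates, path: str | Path) -> None:
    cols = ["x", "y", "z"][: c.d]
    pd.DataFrame(c.positions, index=c.location_ids, columns=cols).to_csv(
        path, sep="\t", index_label="location"
    )


def align(
    counts: CountMatrix, coords: Coordinates, covariates: CovariateTable | None = None
):
    """Reorder coordinates (and covariates) to the counts' location order.

    Location ids are the join key; a mismatched id set raises rather than
    silently intersecting.
    """
    if set(coords.location_ids) != set(counts.location_ids):
        raise AlignmentError("coordinate location ids do not match count matrix")
    order = pd.Index(coords.location_ids).get_indexer(counts.location_ids)
    coords = Coordinates(coords.positions[order], list(counts.location_ids))
    if covariates is None:
        return counts, coords
    if set(covariates.location_ids) != set(counts.location_ids):
        raise AlignmentError("covariate location ids do not match count matrix")
    corder = pd.Index(covariates.location_ids).get_indexer(counts.location_ids)
    cov = CovariateTable(
        covariates.table.iloc[corder], list(counts.location_ids)
    )
    return counts, coords, cov


def filter_genes(
    m: CountMatrix,
    min_locations: int = 1,
    drop_patterns: Sequence[str] = (MITO_PATTERN,),
) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least ``min_locations`` locations
    whose names do not match any of ``drop_patterns`` (case-insensitive regex).
    """
    if min_locations < 1:
        raise ValueError("min_locations must be >= 1")
    nnz = np.diff(m.values.indptr)
    keep = nnz >= min_locations
    regexes = [re.compile(p, re.IGNORECASE) for p in drop_patterns]
    for i, g in enumerate(m.gene_ids):
        if keep[i] and any(r.search(g) for r in regexes):
            keep[i] = False
    if not keep.any():
        raise ValueError("gene filtering removed every gene")
    idx = np.flatnonzero(keep)
    return CountMatrix(
        m.values[idx], [m.gene_ids[i] for i in idx], list(m.location_ids)
    )


def filter_locations(
    m: CountMatrix, c: Coordinates, min_total: int = 1
) -> tuple[CountMatrix, Coordinates]:
    """Drop locations whose total count is below ``min_total`` from both objects."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    if c.location_ids != m.location_ids:
        m, c = align(m, c)
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    keep = np.flatnonzero(totals >= min_total)
    new_ids = [m.location_ids[j] for j in keep]
    return (
        CountMatrix(m.values[:, keep], list(m.gene_ids), new_ids),
        Coordinates(c.positions[keep], new_ids),
    )


def encode_covariates(t: CovariateTable | None, n: int | None = None) -> np.ndarray:
    """Build the n x q covariate design matrix X.

    The first column is the intercept. Categorical / string columns are
    one-hot encoded with the first level dropped as reference. Constant and
    collinear columns are dropped (with a warning) so X has full column rank.
    With ``t=None`` returns the intercept-only design (requires ``n``).
    """
    if t is None:
        if n is None:
            raise ValueError("n required for an intercept-only design")
        return np.ones((n, 1))
    df = t.table
    blocks = [np.ones((len(df), 1))]
    names = ["intercept"]
    for col in df.columns:
        s = df[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = pd.unique(s)
            if len(levels) < 2:
                warnings.warn(f"covariate {col!r} is constant; dropped")
                continue
            dummies = pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
            blocks.append(dummies)
            names.extend(f"{col}[{lv}]" for lv in levels[1:])
        else:
            v = s.to_numpy(dtype=float)[:, None]
            if np.ptp(v) == 0:
                warnings.warn(f"covariate {col!r} is constant; dropped")
                continue
            blocks.append(v)
            names.append(str(col))
    x = np.hstack(blocks)
    # drop collinear columns greedily, keeping the intercept
    keep = [0]
    for j in range(1, x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"covariate column {names[j]!r} is collinear; dropped")
    return x[:, keep]


def write_results(results, path: str | Path) -> None:
    """Write per-gene test results as TSV (one row per gene)."""
    rows = []
    for r in results:
        row = {"gene": r.gene_id}
        for kr in r.per_kernel:
            row[f"p_{kr.label}"] = kr.p
        row["combined_p"] = r.combined_p
        row["adjusted_p"] = r.adjusted_p
        row["status"] = r.status
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
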