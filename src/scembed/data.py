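"""Core data containers and on-disk formats.

The toolkit revolves around four small containers:

``ExpressionMatrix``
    A dense cell x feature matrix of normalized log expression with cell
    metadata (cell type, batch, condition).
``FeatureEmbeddingTable``
    A mapping from feature (gene/protein) names to fixed-length real
    vectors, typically derived from text descriptions of gene function.
``LabelEmbeddingTable``
    The same structure for cell-level metadata labels (e.g. cell types).
``CellEmbeddingMatrix``
    The n x t per-cell embedding produced by aggregation.

On disk, expression matrices live as Matrix Market MTX with ``cells.tsv`` /
``features.tsv`` (+ optional ``metadata.tsv``) sidecars, as dense CSV, or as
AnnData h5ad; embedding tables are plain TSV with the name in the first
column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed as the declared format."""


META_COLUMNS = ("cell_type", "batch", "condition")


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Cell x feature expression matrix with per-cell metadata.

    ``values`` holds nonnegative reals; after :func:`normalize_counts` these
    are log1p of depth-normalized counts and ``normalized`` is True.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    cell_meta: pd.DataFrame = field(default=None)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if scipy.sparse.issparse(self.values):  # pragma: no cover - asarray densifies
            self.values = self.values.toarray()
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.feature_ids):
            raise ValidationError(
                f"matrix has {m} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.feature_ids, "feature ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("expression values must be nonnegative")
        if set(self.cell_meta.index) - set(self.cell_ids):
            raise ValidationError("cell_meta contains rows for unknown cell ids")
        # keep metadata aligned to cell order
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        self.cell_meta.index.name = "cell_id"

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def meta_column(self, name: str) -> list:
        if name not in self.cell_meta.columns:
            raise KeyError(f"cell_meta has no column {name!r}")
        return list(self.cell_meta[name])

    def subset_features(self, features: list[str]) -> "ExpressionMatrix":
        """Column subset (and reorder) by feature name."""
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in pos]
        if missing:
            raise ValidationError(f"unknown features: {missing[:20]}")
        idx = [pos[f] for f in features]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            feature_ids=list(features),
            cell_meta=self.cell_meta.copy(),
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            feature_ids=list(self.feature_ids),
            cell_meta=self.cell_meta.copy(),
        )


@dataclass
class FeatureEmbeddingTable:
    """Feature name -> t-dimensional vector."""

    names: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        self.names = [str(n) for n in self.names]
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            if self.vectors.size == 0:
                self.vectors = self.vectors.reshape(0, self.vectors.shape[-1] if self.vectors.ndim else 0)
            else:
                raise ValidationError("vectors must be 2-D")
        if self.vectors.shape[0] != len(self.names):
            raise ValidationError(
                f"{len(self.names)} names but {self.vectors.shape[0]} vectors"
            )
        _check_unique(self.names, "feature names")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("embedding vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, names: list[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValidationError(f"names not in table: {missing[:20]}")
        return self.vectors[[pos[n] for n in names]]


class LabelEmbeddingTable(FeatureEmbeddingTable):
    """Label -> vector table for cell-level metadata (cell types, states)."""

    @property
    def labels(self) -> list[str]:
        return self.names


@dataclass
class CellEmbeddingMatrix:
    """n x t per-cell embedding."""

    cell_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValidationError("cell embedding vectors must be 2-D")
        if self.vectors.shape[0] != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids but {self.vectors.shape[0]} rows"
            )
        _check_unique(self.cell_ids, "cell ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("cell embeddings must be finite")

    @property
    def n_cells(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------

def _mtx_paths(path: str):
    d = path if os.path.isdir(path) else os.path.dirname(os.path.abspath(path))
    mtx = path if path.endswith(".mtx") else os.path.join(d, "matrix.mtx")
    return (
        mtx,
        os.path.join(d, "cells.tsv"),
        os.path.join(d, "features.tsv"),
        os.path.join(d, "metadata.tsv"),
    )


def _read_meta(path: str) -> pd.DataFrame | None:
    if not os.path.exists(path):
        return None
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise FormatError(f"{path}: metadata must have a cell_id column")
    return meta.set_index("cell_id")


def read_expression(path: str, format: str = None, normalized: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from ``mtx``, ``csv`` or ``h5ad``.

    For MTX, ``path`` may be the .mtx file or its directory; ``cells.tsv`` and
    ``features.tsv`` sidecars (one id per line) must sit alongside, and an
    optional ``metadata.tsv`` (with a ``cell_id`` column) supplies cell
    metadata. For CSV the header row holds feature names and the first column
    cell ids; an optional ``<file>.meta.tsv`` sidecar supplies metadata.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".mtx": "mtx", ".csv": "csv", ".h5ad": "h5ad"}.get(ext, "mtx" if os.path.isdir(path) else None)
        if format is None:
            raise FormatError(f"cannot infer format of {path}")

    if format == "mtx":
        mtx, cells_f, feats_f, meta_f = _mtx_paths(path)
        for f, what in ((mtx, "matrix"), (cells_f, "cell id sidecar"), (feats_f, "feature id sidecar")):
            if not os.path.exists(f):
                raise FormatError(f"missing {what} file: {f}")
        mm = scipy.io.mmread(mtx)
        values = np.asarray(mm.todense() if scipy.sparse.issparse(mm) else mm, dtype=float)
        cell_ids = pd.read_csv(cells_f, sep="\t", header=None)[0].astype(str).tolist()
        feature_ids = pd.read_csv(feats_f, sep="\t", header=None)[0].astype(str).tolist()
        meta = _read_meta(meta_f)
        return ExpressionMatrix(values, cell_ids, feature_ids, meta, normalized=normalized)

    if format == "csv":
        if not os.path.exists(path):
            raise FormatError(f"missing file: {path}")
        df = pd.read_csv(path, index_col=0)
        meta = _read_meta(path + ".meta.tsv")
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
            meta,
            normalized=normalized,
        )

    if format == "h5ad":
        import anndata

        ad = anndata.read_h5ad(path)
        X = ad.X.toarray() if scipy.sparse.issparse(ad.X) else np.asarray(ad.X)
        meta_cols = [c for c in META_COLUMNS if c in ad.obs.columns]
        meta = ad.obs[meta_cols].astype(str) if meta_cols else None
        if meta is not None:
            meta = meta.copy()
            meta.index = ad.obs_names.astype(str)
            meta.index.name = "cell_id"
        return ExpressionMatrix(
            X, ad.obs_names.astype(str).tolist(), ad.var_names.astype(str).tolist(),
            meta, normalized=normalized,
        )

    raise FormatError(f"unknown format {format!r}")


def write_expression(x: ExpressionMatrix, path: str, format: str = "mtx") -> None:
    """Write an expression matrix; ``read_expression`` round-trips it."""
    x.validate()
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        mtx, cells_f, feats_f, meta_f = _mtx_paths(path)
        scipy.io.mmwrite(mtx, scipy.sparse.coo_matrix(x.values), precision=17)
        pd.Series(x.cell_ids).to_csv(cells_f, sep="\t", header=False, index=False)
        pd.Series(x.feature_ids).to_csv(feats_f, sep="\t", header=False, index=False)
        if len(x.cell_meta.columns):
            x.cell_meta.to_csv(meta_f, sep="\t")
    elif format == "csv":
        df = pd.DataFrame(x.values, index=x.cell_ids, columns=x.feature_ids)
        df.index.name = "cell_id"
        df.to_csv(path)
        if len(x.cell_meta.columns):
            x.cell_meta.to_csv(path + ".meta.tsv", sep="\t")
    elif format == "h5ad":
        import anndata

        ad = anndata.AnnData(
            X=np.asarray(x.values),
            obs=x.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(x.feature_ids, name="feature_id")),
        )
        ad.obs_names = x.cell_ids
        ad.write_h5ad(path)
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# embedding-table I/O
# ---------------------------------------------------------------------------

def read_embedding_table(path: str, header: bool = True) -> FeatureEmbeddingTable:
    """Read a name + t numeric columns TSV into a FeatureEmbeddingTable."""
    if not os.path.exists(path):
        raise FormatError(f"missing file: {path}")
    names, rows, width = [], [], None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if header and lines:
        lines = lines[1:]
    for i, ln in enumerate(lines, start=2 if header else 1):
        parts = ln.split("\t")
        if width is None:
            width = len(parts)
            if width < 2:
                raise FormatError(f"{path}: row {i}: need a name plus >=1 numeric column")
        elif len(parts) != width:
            raise FormatError(f"{path}: ragged row {i} ({len(parts)} fields, expected {width})")
        names.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as e:
            raise FormatError(f"{path}: row {i}: {e}") from None
    vectors = np.array(rows, dtype=float) if rows else np.zeros((0, (width or 1) - 1))
    return FeatureEmbeddingTable(names, vectors)


def write_embedding_table(tab: FeatureEmbeddingTable, path: str) -> None:
    """Write a FeatureEmbeddingTable as TSV at full float precision."""
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(f"d{i}" for i in range(tab.dim)) + "\n")
        for name, vec in zip(tab.names, tab.vectors):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def write_cell_embeddings(emb: CellEmbeddingMatrix, path: str) -> None:
    write_embedding_table(FeatureEmbeddingTable(emb.cell_ids, emb.vectors), path)


def read_cell_embeddings(path: str) -> CellEmbeddingMatrix:
    tab = read_embedding_table(path)
    return CellEmbeddingMatrix(tab.names, tab.vectors)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_counts(raw: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize each cell to ``target_sum`` total counts, then log1p.

    Cells with zero total counts are kept and stay all-zero. The returned
    matrix has ``normalized=True``.
    """
    if raw.normalized:
        raise ValidationError("matrix is already normalized")
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    totals = raw.values.sum(axis=1, keepdims=True)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    values = np.log1p(raw.values * scale)
    return ExpressionMatrix(
        values, list(raw.cell_ids), list(raw.feature_ids), raw.cell_meta.copy(),
        normalized=True,
    )
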