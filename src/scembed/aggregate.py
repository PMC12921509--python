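"""Aggregation of feature embeddings into cell embeddings.

A cell's embedding is a weighted sum of the embeddings of its features,

    e_cells = AVG(X) @ e_f  (+ e_c, optionally),

where ``AVG`` is one of two weighting modes applied to the normalized
expression matrix X (n cells x m features):

``aa`` (arithmetic average)
    every entry divided by m, so all features contribute on the same scale;
``wa`` (weighted average)
    each row divided by its own sum, so weights sum to 1 per cell and the
    embedding is a convex combination of feature vectors, invariant to
    per-cell scaling.

``wa`` is the recommended mode for clustering/integration/annotation; ``aa``
distributes contributions evenly and suits perturbation-style exports.
Cell-level label embeddings (e_c), when supplied, are added after
aggregation as a pure vector sum.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import (
    CellEmbeddingMatrix,
    ExpressionMatrix,
    FeatureEmbeddingTable,
    LabelEmbeddingTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODES = ("aa", "wa")

#: task-appropriate defaults; wa for representation tasks, aa for exports
DEFAULT_MODE = "wa"
DEFAULT_PERTURBATION_MODE = "aa"


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")


def avg_weights(x: ExpressionMatrix, mode: str) -> np.ndarray:
    """The n x m weight matrix AVG(X) for the given mode.

    Rows with zero total under ``wa`` have no defined convex weighting; they
    get an all-zero weight row (and hence a zero embedding), with a warning.
    """
    _check_mode(mode)
    if mode == "aa":
        return x.values / x.n_features
    totals = x.values.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(totals[:, 0] == 0)
    if zero_rows.size:
        logger.warning(
            "wa weights: %d cell(s) with zero total expression get zero "
            "embeddings: %s",
            zero_rows.size,
            [x.cell_ids[i] for i in zero_rows[:10]],
        )
    return np.divide(x.values, totals, out=np.zeros_like(x.values), where=totals > 0)


def cell_embeddings(
    x: ExpressionMatrix,
    feats: FeatureEmbeddingTable,
    mode: str = DEFAULT_MODE,
    labels: list[str] | None = None,
    label_tab: LabelEmbeddingTable | None = None,
    intersect: bool = False,
) -> CellEmbeddingMatrix:
    """Aggregate feature embeddings into per-cell embeddings.

    Feature columns are aligned to the embedding table by *name*. Every
    feature of ``x`` must be present in ``feats`` unless ``intersect=True``,
    in which case the expression matrix is restricted to the shared features
    (a warning lists how many were dropped). If per-cell ``labels`` and a
    ``label_tab`` are given, each cell's label vector is added to its
    aggregated embedding.
    """
    _check_mode(mode)
    have = set(feats.names)
    missing = [f for f in x.feature_ids if f not in have]
    if missing:
        if not intersect:
            raise ValidationError(
                f"{len(missing)} feature(s) missing from embedding table "
                f"(pass intersect=True to drop them): {missing[:20]}"
            )
        shared = [f for f in x.feature_ids if f in have]
        if not shared:
            raise ValidationError("no features shared with the embedding table")
        logger.warning(
            "dropping %d/%d features absent from the embedding table",
            len(missing), x.n_features,
        )
        x = x.subset_features(shared)
    E = feats.lookup(x.feature_ids)
    out = avg_weights(x, mode) @ E
    if labels is not None:
        if label_tab is None:
            raise ValidationError("labels supplied without a label embedding table")
        if len(labels) != x.n_cells:
            raise ValidationError("one label per cell required")
        if label_tab.dim != feats.dim:
            raise ValidationError(
                f"label table dim {label_tab.dim} != feature table dim {feats.dim}"
            )
        out = out + label_tab.lookup([str(l) for l in labels])
    elif label_tab is not None:
        raise ValidationError("label table supplied without per-cell labels")
    return CellEmbeddingMatrix(list(x.cell_ids), out)


def delete_genes(x: ExpressionMatrix, genes) -> ExpressionMatrix:
    """Zero the expression of the named genes (in-silico deletion).

    Columns are zeroed, not removed, so embedding dimensions stay aligned;
    under ``wa`` the remaining weights re-normalize automatically because row
    sums are recomputed on the zeroed matrix.
    """
    genes = set(genes)
    unknown = genes - set(x.feature_ids)
    if unknown:
        raise ValidationError(f"unknown gene(s): {sorted(unknown)[:20]}")
    out = x.copy()
    idx = [j for j, f in enumerate(x.feature_ids) if f in genes]
    out.values[:, idx] = 0.0
    return out


def combine_tables(
    a: FeatureEmbeddingTable, b: FeatureEmbeddingTable, how: str = "sum"
) -> FeatureEmbeddingTable:
    """Sum or concatenate two embedding tables over their shared names."""
    shared = [n for n in a.names if n in set(b.names)]
    if not shared:
        raise ValidationError("tables share no names")
    va, vb = a.lookup(shared), b.lookup(shared)
    if how == "sum":
        if a.dim != b.dim:
            raise ValidationError("sum requires equal dims")
        return FeatureEmbeddingTable(shared, va + vb)
    if how == "concat":
        return FeatureEmbeddingTable(shared, np.hstack([va, vb]))
    raise ValidationError(f"how must be 'sum' or 'concat', got {how!r}")
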