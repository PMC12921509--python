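"""In-silico treatment analysis: gene-deletion target screening.

A gene g is scored by how much deleting it (zeroing its expression column)
moves the diseased cells' mean embedding toward the control cells' mean
embedding:

    Score(g) = CS_new - CS_old,

where CS_old is the cosine similarity between the mean diseased and mean
control cell embeddings, and CS_new is the same quantity after deletion and
re-aggregation (and re-embedding through the same trained adaptor when one
is supplied — no retraining). Genes with Score(g) strictly above 1e-4 are
flagged as candidate therapeutic targets. Candidates default to the top 10
differentially expressed genes between the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .adaptor import TrainedAdaptor, adaptor_embed
from .aggregate import cell_embeddings, delete_genes
from .data import CellEmbeddingMatrix, ExpressionMatrix, FeatureEmbeddingTable, ValidationError

#: strict score threshold for calling a gene a candidate target
CANDIDATE_THRESHOLD = 1e-4


def _condition_masks(condition_labels, diseased, control, n):
    labels = np.asarray([str(l) for l in condition_labels])
    if labels.shape[0] != n:
        raise ValidationError("one condition label per cell required")
    dis, ctl = labels == str(diseased), labels == str(control)
    if not dis.any():
        raise ValidationError(f"no cells with condition {diseased!r}")
    if not ctl.any():
        raise ValidationError(f"no cells with condition {control!r}")
    return dis, ctl


def select_top_degs(
    x: ExpressionMatrix,
    condition_labels,
    diseased: str,
    control: str,
    n_top: int = 10,
) -> list[str]:
    """Top differentially expressed genes between two conditions.

    Per-gene two-sided Wilcoxon rank-sum test, Benjamini-Hochberg adjusted,
    ranked by adjusted p-value then |mean log-expression difference|.
    """
    dis, ctl = _condition_masks(condition_labels, diseased, control, x.n_cells)
    if dis.sum() < 2 or ctl.sum() < 2:
        raise ValidationError("each condition needs >= 2 cells")
    pvals = np.empty(x.n_features)
    for j in range(x.n_features):
        a, b = x.values[dis, j], x.values[ctl, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[j] = 1.0
        else:
            pvals[j] = scipy.stats.ranksums(a, b).pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    diff = np.abs(x.values[dis].mean(axis=0) - x.values[ctl].mean(axis=0))
    order = np.lexsort((-diff, padj))
    return [x.feature_ids[j] for j in order[:n_top]]


def condition_cosine(
    emb: CellEmbeddingMatrix, condition_labels, diseased: str, control: str
) -> float:
    """Cosine similarity between mean diseased and mean control embeddings."""
    dis, ctl = _condition_masks(condition_labels, diseased, control, emb.n_cells)
    mu_d = emb.vectors[dis].mean(axis=0)
    mu_c = emb.vectors[ctl].mean(axis=0)
    nd, nc = np.linalg.norm(mu_d), np.linalg.norm(mu_c)
    if nd == 0 or nc == 0:
        raise ValidationError("a condition mean embedding is the zero vector")
    return float(mu_d @ mu_c / (nd * nc))


def _embed(x, feats, mode, model):
    emb = cell_embeddings(x, feats, mode)
    if model is not None:
        emb = adaptor_embed(model, emb)
    return emb


def score_gene(
    g: str,
    x: ExpressionMatrix,
    feats: FeatureEmbeddingTable,
    condition_labels,
    diseased: str,
    control: str,
    mode: str = "wa",
    model: TrainedAdaptor | None = None,
    cs_old: float | None = None,
):
    """(CS_old, CS_new, score) for deleting gene ``g``.

    The deletion pipeline re-aggregates the zeroed matrix (under ``wa`` the
    row sums are recomputed after zeroing) and, when a trained adaptor is
    given, re-embeds with the same parameters — no retraining. ``cs_old``
    may be passed to reuse a precomputed baseline.
    """
    if g not in x.feature_ids:
        raise ValidationError(f"unknown gene {g!r}")
    if cs_old is None:
        cs_old = condition_cosine(
            _embed(x, feats, mode, model), condition_labels, diseased, control
        )
    emb_new = _embed(delete_genes(x, {g}), feats, mode, model)
    cs_new = condition_cosine(emb_new, condition_labels, diseased, control)
    return cs_old, cs_new, cs_new - cs_old


@dataclass
class TargetScreen:
    """Model object for the screen: data in, ``fit()`` -> score table."""

    x: ExpressionMatrix
    feats: FeatureEmbeddingTable
    condition_labels: list
    diseased: str
    control: str
    mode: str = "wa"
    model: TrainedAdaptor | None = None
    candidates: list[str] | None = None
    n_top: int = 10
    threshold: float = CANDIDATE_THRESHOLD

    def fit(self) -> pd.DataFrame:
        return screen_targets(
            self.x, self.feats, self.condition_labels, self.diseased,
            self.control, mode=self.mode, model=self.model,
            candidates=self.candidates, n_top=self.n_top,
            threshold=self.threshold,
        )


def screen_targets(
    x: ExpressionMatrix,
    feats: FeatureEmbeddingTable,
    condition_labels,
    diseased: str,
    control: str,
    mode: str = "wa",
    model: TrainedAdaptor | None = None,
    candidates: list[str] | None = None,
    n_top: int = 10,
    threshold: float = CANDIDATE_THRESHOLD,
) -> pd.DataFrame:
    """Score every candidate gene; flag candidates with score > threshold.

    Returns a DataFrame with columns gene, cs_old, cs_new, score,
    is_candidate, sorted by score descending.
    """
    if candidates is None:
        candidates = select_top_degs(x, condition_labels, diseased, control, n_top)
    cs_old = condition_cosine(
        _embed(x, feats, mode, model), condition_labels, diseased, control
    )
    rows = []
    for g in candidates:
        _, cs_new, score = score_gene(
            g, x, feats, condition_labels, diseased, control,
            mode=mode, model=model, cs_old=cs_old,
        )
        rows.append(
            {
                "gene": g,
                "cs_old": cs_old,
                "cs_new": cs_new,
                "score": score,
                "is_candidate": bool(score > threshold),
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "cs_old", "cs_new", "score", "is_candidate"])
    return table.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
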