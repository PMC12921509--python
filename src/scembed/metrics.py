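"""Evaluation metrics for clustering, integration, annotation and prediction.

Bio-conservation metrics (higher = better biology kept):

* ``nmi`` / ``ari`` — agreement between Leiden clusters and known labels;
* ``asw_label`` — mean silhouette width s, reported as (s + 1) / 2;
* cLISI — 1 − (rawLISI − 1)/(C − 1) on cell-type labels.

Batch-mixing metrics (higher = better mixing):

* ``asw_batch`` — 1 − (s + 1)/2 on batch labels;
* iLISI — (rawLISI − 1)/(B − 1) on batch labels;
* ``graph_connectivity`` — per cell type, the largest connected component
  fraction of the type-induced kNN subgraph, averaged over types;
* ``pc_regression_score`` — 1 minus the PC-variance-weighted R² of batch
  onto each principal component;
* ``kbet_score`` — fraction of cells whose neighborhood batch composition
  passes a chi-squared goodness-of-fit test against the global composition.

The raw LISI here is the simplified walk count: traverse a cell's
distance-sorted neighbor list and count neighbors extracted before any label
would be observed a second time.

Composites average their components: S_batch = mean(ASW_batch, PCR, GC,
kBET, iLISI) and S_bio = mean(ASW_label, NMI, ARI, cLISI), with negative ARI
clipped to 0 inside the composite only.

Also included: clipped single-n BLEU for text comparison, macro-averaged
classification scores, and R²/PCC/MSE for expression prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import scipy.sparse
import scipy.stats
from scipy.sparse.csgraph import connected_components
from sklearn import metrics as skm
from sklearn.decomposition import PCA

from .data import ValidationError
from .zeroshot import NeighborGraph, cluster_cells, knn_graph, _as_array

logger = logging.getLogger(__name__)


def _check_paired(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValidationError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return a, b


# ---------------------------------------------------------------------------
# clustering / bio conservation
# ---------------------------------------------------------------------------

def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    a, b = _check_paired(labels_a, labels_b)
    return float(skm.normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (pair-counting closed form; may be negative)."""
    a, b = _check_paired(labels_a, labels_b)
    return float(skm.adjusted_rand_score(a, b))


def _silhouette(emb, labels) -> float:
    X = _as_array(emb)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("silhouette needs >= 2 distinct labels")
    return float(skm.silhouette_score(X, labels, metric="euclidean"))


def asw_label(emb, labels) -> float:
    """Cell-type silhouette mapped to [0, 1]: (s + 1) / 2."""
    return (_silhouette(emb, labels) + 1.0) / 2.0


def asw_batch(emb, batch_labels, per_type_labels=None) -> float:
    """Batch silhouette, inverted so 1 = perfectly mixed: 1 − (s + 1)/2.

    With ``per_type_labels`` the score is computed within each cell type and
    averaged (types with a single batch are skipped).
    """
    if per_type_labels is None:
        return 1.0 - (_silhouette(emb, batch_labels) + 1.0) / 2.0
    X = _as_array(emb)
    batch_labels = np.asarray(batch_labels)
    per_type_labels = np.asarray(per_type_labels)
    scores = []
    for t in np.unique(per_type_labels):
        mask = per_type_labels == t
        if len(set(batch_labels[mask].tolist())) < 2 or mask.sum() < 3:
            continue
        scores.append(1.0 - (_silhouette(X[mask], batch_labels[mask]) + 1.0) / 2.0)
    if not scores:
        raise ValidationError("no cell type contains >= 2 batches")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# LISI (simplified walk)
# ---------------------------------------------------------------------------

def lisi_raw(graph: NeighborGraph, labels) -> float:
    """Mean, over cells, of the walk count on distance-sorted neighbors.

    For one cell: extract neighbors in order, stopping just before any label
    would appear a second time; the count of extracted neighbors is that
    cell's value (at least 1 when the list is nonempty).
    """
    labels = np.asarray(labels)
    counts = np.empty(graph.n)
    for i in range(graph.n):
        seen = set()
        c = 0
        for j in graph.indices[i]:
            l = labels[j]
            if l in seen:
                break
            seen.add(l)
            c += 1
        counts[i] = c
    return float(counts.mean())


def lisi(graph: NeighborGraph, labels, mode: str, n_classes: int | None = None) -> float:
    """Normalized LISI: iLISI = (raw−1)/(B−1); cLISI = 1 − (raw−1)/(C−1).

    Both are clipped to [0, 1]; higher is better in both orientations.
    """
    if mode not in ("ilisi", "clisi"):
        raise ValidationError("mode must be 'ilisi' or 'clisi'")
    labels = np.asarray(labels)
    B = n_classes if n_classes is not None else len(set(labels.tolist()))
    if B < 2:
        raise ValidationError("LISI normalization needs >= 2 classes")
    raw = lisi_raw(graph, labels)
    score = (raw - 1.0) / (B - 1.0)
    if mode == "clisi":
        score = 1.0 - score
    return float(np.clip(score, 0.0, 1.0))


# ---------------------------------------------------------------------------
# graph connectivity
# ---------------------------------------------------------------------------

def graph_connectivity(graph: NeighborGraph, type_labels) -> float:
    """Mean over cell types of |largest component| / |type| on the
    type-induced undirected kNN subgraph."""
    labels = np.asarray(type_labels)
    if labels.shape[0] != graph.n:
        raise ValidationError("one label per cell required")
    edges = graph.edges()
    scores = []
    for t in np.unique(labels):
        nodes = np.flatnonzero(labels == t)
        if nodes.size == 1:
            scores.append(1.0)
            continue
        pos = {v: i for i, v in enumerate(nodes)}
        sub = [(pos[a], pos[b]) for a, b in edges if a in pos and b in pos]
        if sub:
            rows, cols = zip(*sub)
            A = scipy.sparse.coo_matrix(
                (np.ones(len(sub)), (rows, cols)), shape=(nodes.size, nodes.size)
            )
        else:
            A = scipy.sparse.coo_matrix((nodes.size, nodes.size))
        _, comp = connected_components(A, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / nodes.size)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# principal-component regression
# ---------------------------------------------------------------------------

def pcr_batch_variance(X, batch_labels, n_pcs: int = 50) -> float:
    """Batch-explained variance: sum over PCs of (variance fraction of the
    PC) x (R² of regressing the PC score on batch indicators)."""
    X = _as_array(X)
    batch_labels = np.asarray(batch_labels)
    classes = np.unique(batch_labels)
    if classes.size < 2:
        raise ValidationError("PCR needs >= 2 batches")
    n_pcs = min(n_pcs, min(X.shape) - 1)
    if n_pcs < 1:
        raise ValidationError("not enough dimensions for PCA")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    varfrac = pca.explained_variance_ratio_
    # one-hot batch design with intercept; R^2 via projection
    Z = np.column_stack([np.ones(X.shape[0])] + [
        (batch_labels == c).astype(float) for c in classes[:-1]
    ])
    beta, *_ = np.linalg.lstsq(Z, scores, rcond=None)
    fitted = Z @ beta
    ss_res = ((scores - fitted) ** 2).sum(axis=0)
    ss_tot = ((scores - scores.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)
    return float(np.sum(varfrac * r2))


def pc_regression_score(X, batch_labels, n_pcs: int = 50) -> float:
    """1 − batch-explained variance, clipped to [0, 1]; higher = better."""
    return float(np.clip(1.0 - pcr_batch_variance(X, batch_labels, n_pcs), 0.0, 1.0))


# ---------------------------------------------------------------------------
# kBET
# ---------------------------------------------------------------------------

def kbet_score(graph: NeighborGraph, batch_labels, alpha: float = 0.05) -> float:
    """Neighborhood batch-composition test; score = acceptance rate.

    Per cell, a chi-squared goodness-of-fit test compares the batch counts
    among its k neighbors with the global batch proportions; the score is
    the fraction of cells whose test is NOT rejected at level ``alpha``.
    """
    labels = np.asarray(batch_labels)
    classes, global_counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("kBET needs >= 2 batches")
    if (global_counts == 0).any():
        raise ValidationError("batch with zero global count")
    props = global_counts / global_counts.sum()
    index = {c: i for i, c in enumerate(classes)}
    lab_idx = np.array([index[l] for l in labels])
    k = graph.indices.shape[1]
    accepted = 0
    for i in range(graph.n):
        observed = np.bincount(lab_idx[graph.indices[i]], minlength=classes.size)
        expected = props * k
        stat = ((observed - expected) ** 2 / expected).sum()
        p = scipy.stats.chi2.sf(stat, df=classes.size - 1)
        if p > alpha:  # accept strictly above alpha so alpha=1 rejects all
            accepted += 1
    return accepted / graph.n


# ---------------------------------------------------------------------------
# composite report
# ---------------------------------------------------------------------------

@dataclass
class IntegrationReport:
    """All integration metrics plus the S_batch / S_bio composites."""

    asw_label: float
    nmi: float
    ari: float
    clisi: float
    asw_batch: float
    pcr: float
    gc: float
    kbet: float
    ilisi: float
    s_batch: float
    s_bio: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def summary(self) -> str:
        parts = [f"{k}={v:.3f}" for k, v in self.to_dict().items()]
        return "IntegrationReport(" + ", ".join(parts) + ")"


def integration_report(
    emb,
    type_labels,
    batch_labels,
    k: int = 90,
    kbet_k: int = 50,
    alpha: float = 0.05,
    n_pcs: int = 50,
    seed: int = 0,
    cluster_k: int = 15,
    scan_resolution: bool = False,
) -> IntegrationReport:
    """Compute every integration metric on a shared kNN graph.

    Leiden clustering (for NMI/ARI) runs on the embedding at resolution 1.0,
    or scans resolutions 0.1..2.0 and keeps the best score per metric when
    ``scan_resolution=True``.
    """
    X = _as_array(emb)
    type_labels = np.asarray(type_labels)
    batch_labels = np.asarray(batch_labels)
    n = X.shape[0]
    graph = knn_graph(X, min(k, n - 1))
    kgraph = graph if kbet_k == k else knn_graph(X, min(kbet_k, n - 1))

    if scan_resolution:
        nmi_v, ari_v = 0.0, -1.0
        for res in np.arange(0.1, 2.01, 0.1):
            cl = cluster_cells(X, k=cluster_k, resolution=float(res), seed=seed)
            nmi_v = max(nmi_v, nmi(cl, type_labels))
            ari_v = max(ari_v, ari(cl, type_labels))
    else:
        cl = cluster_cells(X, k=cluster_k, resolution=1.0, seed=seed)
        nmi_v, ari_v = nmi(cl, type_labels), ari(cl, type_labels)

    asw_l = asw_label(X, type_labels)
    asw_b = asw_batch(X, batch_labels)
    clisi_v = lisi(graph, type_labels, "clisi")
    ilisi_v = lisi(graph, batch_labels, "ilisi")
    gc_v = graph_connectivity(graph, type_labels)
    pcr_v = pc_regression_score(X, batch_labels, n_pcs=n_pcs)
    kbet_v = kbet_score(kgraph, batch_labels, alpha=alpha)

    s_batch = float(np.mean([asw_b, pcr_v, gc_v, kbet_v, ilisi_v]))
    s_bio = float(np.mean([asw_l, nmi_v, max(ari_v, 0.0), clisi_v]))
    return IntegrationReport(
        asw_label=asw_l, nmi=nmi_v, ari=ari_v, clisi=clisi_v,
        asw_batch=asw_b, pcr=pcr_v, gc=gc_v, kbet=kbet_v, ilisi=ilisi_v,
        s_batch=s_batch, s_bio=s_bio,
    )


# ---------------------------------------------------------------------------
# text / classification / regression metrics
# ---------------------------------------------------------------------------

def _tokens(x, n_lower=True):
    if isinstance(x, str):
        x = x.lower().split() if n_lower else x.split()
    return list(x)


def bleu_n(candidate, reference, n: int = 1) -> float:
    """Clipped n-gram precision of the candidate against one reference.

    Strings are lowercased and whitespace-tokenized; token lists pass
    through. A candidate shorter than n tokens scores 0 by convention.
    """
    if n <= 0:
        raise ValidationError("n must be >= 1")
    cand, ref = _tokens(candidate), _tokens(reference)
    if len(cand) < n:
        return 0.0

    def grams(toks):
        counts: dict[tuple, int] = {}
        for i in range(len(toks) - n + 1):
            g = tuple(toks[i : i + n])
            counts[g] = counts.get(g, 0) + 1
        return counts

    c_cand, c_ref = grams(cand), grams(ref)
    total = sum(c_cand.values())
    clipped = sum(min(c, c_ref.get(g, 0)) for g, c in c_cand.items())
    return clipped / total


def classification_scores(pred_labels, true_labels, average: str = "macro") -> dict:
    """Accuracy plus macro-averaged precision/recall/F1 over true classes."""
    pred, true = _check_paired(pred_labels, true_labels)
    classes = np.unique(true)
    p, r, f, _ = skm.precision_recall_fscore_support(
        true, pred, labels=classes, average=average, zero_division=0
    )
    return {
        "accuracy": float(skm.accuracy_score(true, pred)),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f),
    }


def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 − SS_res / SS_tot."""
    y, f = _check_paired(np.asarray(y_true, float), np.asarray(y_pred, float))
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValidationError("constant y_true: R2 undefined")
    return float(1.0 - ((y - f) ** 2).sum() / ss_tot)


def pcc_genes(y_true, y_pred) -> float:
    """Mean per-gene Pearson correlation between two cells x genes matrices.

    Genes constant in either matrix are skipped with a warning.
    """
    y = np.asarray(y_true, float)
    f = np.asarray(y_pred, float)
    if y.shape != f.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {f.shape}")
    vals, skipped = [], 0
    for j in range(y.shape[1]):
        if y[:, j].std() == 0 or f[:, j].std() == 0:
            skipped += 1
            continue
        vals.append(scipy.stats.pearsonr(y[:, j], f[:, j]).statistic)
    if skipped:
        logger.warning("pcc_genes: skipped %d zero-variance gene(s)", skipped)
    if not vals:
        raise ValidationError("all genes have zero variance")
    return float(np.mean(vals))


def mse_genes(y_true, y_pred) -> float:
    """Mean squared error over all entries of two cells x genes matrices."""
    y = np.asarray(y_true, float)
    f = np.asarray(y_pred, float)
    if y.shape != f.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {f.shape}")
    return float(((y - f) ** 2).mean())
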