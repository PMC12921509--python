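"""Seeded synthetic data with the structure the pipeline assumes.

Two coupled modalities are generated from one specification:

* a feature-embedding table with *gene-group block structure* — each gene's
  vector mixes a shared group anchor with private noise, emulating how
  functionally related genes receive nearby text-derived embeddings;
* an expression matrix where each cell type elevates the genes of its
  associated group (negative-binomial counts around a log-scale program,
  then depth-normalized and log1p'd), with optional additive log-scale
  batch offsets and per-cell library-size variation.

The same gene groups drive both modalities, which is exactly the premise
the aggregation method relies on: expression weights concentrated on a
functional group pull the cell embedding toward that group's anchor.

``synth_disease`` additionally plants driver genes: diseased cells carry a
strong log-scale shift on each driver plus a proportionally weaker shift on
a small downstream module (20% of one gene group), so that zeroing a driver
moves the diseased mean embedding measurably toward the control mean while
single downstream-module deletions stay below the candidate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, FeatureEmbeddingTable, ValidationError, normalize_counts

#: fraction of the driver-associated gene group that responds to the driver
DRIVER_MODULE_FRACTION = 0.2
#: per-module-gene shift as a fraction of the driver's own shift
DRIVER_MODULE_COUPLING = 0.1


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings; defaults give a cleanly separable 4-type dataset.

    ``type_separation`` is the natural-log mean shift of a type's program
    genes; ``batch_shift`` the additive per-batch log offset (a capture-
    efficiency difference); ``group_coherence`` the anchor weight in gene
    embeddings (1 = identical within group); ``nb_dispersion`` the negative
    binomial shape (larger = closer to Poisson).
    """

    n_cells: int = 600
    n_genes: int = 200
    n_cell_types: int = 4
    n_batches: int = 1
    n_gene_groups: int = 4
    embed_dim: int = 64
    type_separation: float = 2.0
    batch_shift: float = 0.0
    group_coherence: float = 0.8
    nb_dispersion: float = 10.0
    library_sigma: float = 0.3
    planted_driver_genes: int = 0
    driver_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for f in ("n_cells", "n_genes", "n_cell_types", "n_batches", "n_gene_groups", "embed_dim"):
            if getattr(self, f) < 1:
                raise ValidationError(f"{f} must be >= 1")
        if not 0.0 <= self.group_coherence <= 1.0:
            raise ValidationError("group_coherence must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.planted_driver_genes < 0:
            raise ValidationError("planted_driver_genes must be >= 0")


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def gene_names(spec: SynthSpec) -> list[str]:
    return [f"G{j:04d}" for j in range(spec.n_genes)]


def gene_groups(spec: SynthSpec) -> np.ndarray:
    """Contiguous block assignment of genes to groups."""
    return (np.arange(spec.n_genes) * spec.n_gene_groups) // spec.n_genes


def synth_feature_embeddings(spec: SynthSpec):
    """Embedding table with group-block structure; returns (table, groups).

    vector_g = normalize(c * anchor_{group(g)} + (1 - c) * noise_g), with
    unit-norm anchors and noise; c = ``group_coherence``.
    """
    rng = _rng(spec, 1)
    groups = gene_groups(spec)
    anchors = rng.standard_normal((spec.n_gene_groups, spec.embed_dim))
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    noise = rng.standard_normal((spec.n_genes, spec.embed_dim))
    noise /= np.linalg.norm(noise, axis=1, keepdims=True)
    c = spec.group_coherence
    vectors = c * anchors[groups] + (1.0 - c) * noise
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    vectors = np.divide(vectors, norms, out=vectors, where=norms > 0)
    return FeatureEmbeddingTable(gene_names(spec), vectors), groups


def _log_means(spec: SynthSpec, rng: np.random.Generator):
    """Per-cell log-scale mean matrix plus cell type/batch assignments."""
    groups = gene_groups(spec)
    base = rng.normal(0.0, 0.5, size=spec.n_genes)
    types = np.arange(spec.n_cells) % spec.n_cell_types
    batches = (np.arange(spec.n_cells) // spec.n_cell_types) % spec.n_batches
    programs = np.tile(base, (spec.n_cell_types, 1))
    for t in range(spec.n_cell_types):
        programs[t, groups == (t % spec.n_gene_groups)] += spec.type_separation
    mu = programs[types].copy()
    if spec.n_batches > 1 and spec.batch_shift > 0:
        # per-batch scalar log offset: batches past the first have
        # progressively lower capture efficiency, which survives depth
        # normalization as a sparsity / total-log-expression difference
        mu += -spec.batch_shift * batches[:, None]
    if spec.library_sigma > 0:
        mu += rng.normal(0.0, spec.library_sigma, size=(spec.n_cells, 1))
    return mu, types, batches, programs


def _sample_counts(mu, spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """NB counts with mean exp(mu) and shape ``nb_dispersion``."""
    mean = np.exp(mu)
    theta = spec.nb_dispersion
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(float)


def _assemble(counts, types, batches, spec: SynthSpec, prefix="C", condition=None):
    cell_ids = [f"{prefix}{i:05d}" for i in range(counts.shape[0])]
    meta = pd.DataFrame(
        {
            "cell_type": [f"type{t}" for t in types],
            "batch": [f"batch{b}" for b in batches],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if condition is not None:
        meta["condition"] = condition
    raw = ExpressionMatrix(counts, cell_ids, gene_names(spec), meta, normalized=False)
    return normalize_counts(raw)


def synth_expression(spec: SynthSpec):
    """Normalized expression with cell_type/batch metadata.

    Returns ``(ExpressionMatrix, truth)`` where ``truth`` holds the type
    programs, gene groups and assignments.
    """
    rng = _rng(spec, 2)
    mu, types, batches, programs = _log_means(spec, rng)
    counts = _sample_counts(mu, spec, rng)
    x = _assemble(counts, types, batches, spec)
    truth = {
        "programs": programs,
        "gene_groups": gene_groups(spec),
        "cell_types": types,
        "batches": batches,
    }
    return x, truth


def synth_disease(spec: SynthSpec):
    """Control + diseased cells with planted driver genes.

    Control cells follow ``synth_expression``'s model; diseased cells share
    the same type structure but add ``driver_effect`` to each driver gene's
    log mean and ``DRIVER_MODULE_COUPLING * driver_effect`` to each gene of
    a correlated downstream module (a fixed 20% slice of the last gene
    group, disjoint from the drivers). Returns ``(ExpressionMatrix,
    driver_names)``; the matrix carries a ``condition`` metadata column
    with values ``control`` / ``disease``.
    """
    if spec.planted_driver_genes < 1:
        raise ValidationError("planted_driver_genes must be >= 1 for synth_disease")
    rng = _rng(spec, 3)
    groups = gene_groups(spec)
    names = gene_names(spec)
    last_group = np.flatnonzero(groups == spec.n_gene_groups - 1)
    if last_group.size < spec.planted_driver_genes + 1:
        raise ValidationError("last gene group too small to host drivers and module")
    drivers = last_group[: spec.planted_driver_genes]
    rest = last_group[spec.planted_driver_genes :]
    n_module = max(1, int(round(DRIVER_MODULE_FRACTION * last_group.size)))
    module = rest[:n_module]

    mu, types, batches, _ = _log_means(spec, rng)
    counts_ctl = _sample_counts(mu, spec, rng)
    mu_dis = mu.copy()
    mu_dis[:, drivers] += spec.driver_effect
    mu_dis[:, module] += DRIVER_MODULE_COUPLING * spec.driver_effect
    counts_dis = _sample_counts(mu_dis, spec, rng)

    counts = np.vstack([counts_ctl, counts_dis])
    types2 = np.concatenate([types, types])
    batches2 = np.concatenate([batches, batches])
    condition = ["control"] * spec.n_cells + ["disease"] * spec.n_cells
    x = _assemble(counts, types2, batches2, spec, condition=condition)
    return x, [names[j] for j in drivers]


def batch_pair_spec(spec: SynthSpec, batch_shift: float) -> SynthSpec:
    """Convenience: same spec with 2 batches and the given shift."""
    return replace(spec, n_batches=2, batch_shift=batch_shift)
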