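# Methods

## Model

The package turns two inputs — a normalized cell × feature expression
matrix `X` (n × m) and a table of per-feature embedding vectors
`e_f` (m × t), typically derived from text descriptions of gene function —
into per-cell embeddings

    e_cells = AVG(X) · e_f  (+ e_c, optionally),

where `AVG` is one of two weighting schemes applied row-wise to `X`:

* **aa** (arithmetic average): every entry divided by `m`. The embedding is
  a uniformly scaled sum of feature vectors, so it grows linearly with a
  cell's total expression.
* **wa** (weighted average): each row divided by its own sum, making the
  embedding a convex combination of feature vectors and therefore invariant
  to any positive per-cell rescaling.

Optional cell-level metadata embeddings `e_c` (one vector per label, e.g.
cell type) are added after aggregation as a plain vector sum, with no
scaling factor. They are only applied when labels are explicitly supplied,
since they act as an evaluation-time probe rather than an inference-time
input.

The wa mode is the default for clustering, integration and annotation: it
keeps quantitative expression weighting while discarding the per-cell scale
factor that batch and protocol differences contaminate. The aa mode is the
default for exports to perturbation-modeling tools, where evenly distributed
feature contributions are preferable.

Assumptions worth stating explicitly: the expression matrix is nonnegative
and already log-normalized (or pre-processed proteomic data flagged as
normalized); feature alignment between matrix and embedding table is by
name, never by position; cells whose expression row sums to zero receive a
zero embedding under wa (logged as a warning) rather than being dropped,
so row counts stay stable across the pipeline.

## Zero-shot tasks

All zero-shot tasks operate directly on `e_cells`:

* **Neighbor graph.** Exact k-nearest neighbors (Euclidean by default,
  cosine by flag), ties broken by lower cell index so every run is
  deterministic. This one graph underlies clustering, annotation, and the
  graph-based metrics.
* **Clustering.** Leiden community detection (RB-configuration modularity)
  on the kNN graph, k = 15 and resolution 1.0 by default, seeded. For
  *reporting* NMI/ARI against known labels the package follows the
  integration-benchmark convention of scanning resolutions 0.1–2.0 in steps
  of 0.1 and keeping the best score; the scan is an option of the metrics
  module, off by default, because it is an evaluation device rather than an
  analysis step.
* **Annotation.** Majority-vote kNN label transfer with k = 10; the vote
  fraction is reported as a confidence, and ties go to the label of the
  nearest tied neighbor.
* **Integration.** Projection only: each batch is aggregated independently
  over the name-intersected feature set and the rows concatenated. No
  trainable alignment is applied, so any mixing observed is attributable to
  the embedding space itself.

## Metrics

Bio-conservation: NMI (arithmetic normalization), ARI (pair-counting; may
be negative, clipped to 0 only inside the composite), cell-type silhouette
reported as (s̄+1)/2, and cLISI. Batch mixing: batch silhouette reported as
1−(s̄+1)/2, iLISI, graph connectivity (per cell type, the largest connected
component fraction of the type-induced kNN subgraph, averaged), principal-
component regression, and kBET. Composites are exact arithmetic means:
S_batch over {ASW_batch, PCR, GC, kBET, iLISI} and S_bio over {ASW_label,
NMI, ARI⁺, cLISI}.

LISI here is the simplified walk variant, not the inverse-Simpson original:
per cell, traverse the distance-sorted neighbor list and count neighbors
extracted before any label would appear a second time; the mean count is
normalized by (B−1) batches (iLISI) or inverted against (C−1) cell types
(cLISI), then clipped to [0,1]. The walk runs on a k = 90 neighbor list by
default (clipped to n−1); kBET uses k = 50 and a per-neighborhood
chi-squared goodness-of-fit test against global batch proportions at
α = 0.05, reporting the acceptance rate. Acceptance requires p strictly
above α, so α = 1 rejects every neighborhood. These neighborhood sizes are
package defaults, configurable, chosen to match common benchmark practice.

PCR measures the variance fraction of each principal component weighted by
the R² of regressing that component's scores on batch indicators. The raw
sum is batch-explained variance (higher = worse); the reported score is
1 − that sum so that every metric in S_batch reads "higher is better". The
raw quantity is exposed separately.

BLEU is the clipped n-gram precision of a candidate against a single
reference, n = 1 by default with lowercased whitespace tokenization.
Classification scores are accuracy plus macro-averaged precision/recall/F1
over the classes present in the truth (micro by flag). R², per-gene-mean
Pearson correlation, and MSE follow their standard sum-of-squares forms;
genes with zero variance are skipped from the correlation mean with a
warning.

Standard formulas (NMI, ARI, silhouette, precision/recall/F1) delegate to
scikit-learn; the walk LISI, graph connectivity, PCR, kBET and single-n
BLEU are implemented here and validated in the tests against literal
re-implementations (pair-count, entropy, union-find, walk, and loop
oracles).

## Fine-tuning adaptor

A deliberately small feed-forward encoder (default hidden sizes [256, 64],
ReLU) with a linear classifier head is trained on cell embeddings with

    L_total = L_classifier + λ · L_contrastive,   λ = 100 by default.

`L_classifier` is softmax cross-entropy. `L_contrastive` is a supervised
contrastive loss on the L2-normalized last hidden layer: for each anchor
with at least one same-class cell in the mini-batch, the mean over those
positives of −log softmax(z_i·z_p / τ) over all non-anchor similarities,
τ = 0.1. The large λ pushes same-label cells together in the latent space,
which is what downstream kNN annotation and the treatment screen consume;
the classifier head is discarded after training.

Training is plain numpy with hand-derived gradients and Adam (lr 1e-3,
batch 128, 100 epochs by default), seeded end to end, so identical inputs
reproduce parameters and loss traces bit for bit. A stratified 90/10
train/validation split selects the best epoch by validation classifier
loss. Recorded per-epoch losses satisfy total = classifier + λ·contrastive
exactly. Checkpoints are JSON (config manifest plus flat weight arrays) so
they remain portable and human-inspectable.

Design choices that were genuinely open: the contrastive formulation
(supervised contrastive over in-batch positives; an augmentation-based
InfoNCE variant is deliberately not implemented), the architecture depth
and widths, and the optimizer settings. All are configuration keys with the
defaults above.

## In-silico treatment screen

Candidates default to the top 10 differentially expressed genes between the
diseased and control condition (two-sided Wilcoxon rank-sum per gene,
Benjamini–Hochberg adjustment, ranked by adjusted p then absolute mean
log-expression difference). For each candidate g:

1. compute CS_old, the cosine similarity between the mean diseased and mean
   control cell embeddings (raw wa aggregation by default; the fine-tuned
   adaptor latent when a trained model is supplied — the same parameters,
   never retrained);
2. zero g's expression column, re-aggregate (wa row sums are recomputed on
   the zeroed matrix, never cached), re-embed, and compute CS_new;
3. Score(g) = CS_new − CS_old; g is a candidate therapeutic target when the
   score is strictly greater than 1e-4.

Because deletion zeroes the gene in both conditions, a gene expressed
similarly in both shifts both means nearly identically and scores near
zero; only genes with condition-specific expression can move the diseased
mean toward the control mean. Multi-state diseases are handled by running
the screen once per diseased state against the shared control.

## Synthetic data

The generator produces the two coupled modalities the method assumes:

* **Gene embeddings.** Genes are partitioned into contiguous groups; each
  vector is normalize(c·anchor + (1−c)·noise) with unit-norm anchors and
  noise and coherence c = 0.8 by default. Groups emulate functional
  neighborhoods in a text-derived embedding space.
* **Expression.** Each cell type elevates its associated gene group's
  natural-log mean by `type_separation` (default 2.0) over a gene-level
  baseline ~N(0, 0.5); counts are negative binomial (shape 10) with
  per-cell log-normal library variation (σ 0.3), then depth-normalized to
  10,000 and log1p'd. Batches past the first receive a uniform per-batch
  log offset of −`batch_shift` — a capture-efficiency difference that
  survives depth normalization as a sparsity and total-log-expression
  difference, the component of real batch effects that wa removes and aa
  keeps. The integration tests use batch_shift = 2.0 (≈7× capture
  difference) to emulate a cross-protocol scenario.
* **Disease.** Control cells follow the expression model; diseased cells
  add `driver_effect` (3.0 in the reference condition) to each planted
  driver gene's log mean and 0.1·driver_effect to each gene of a downstream
  module (a fixed 20% slice of the driver's gene group). The module
  coupling is set so that deleting the driver moves the diseased mean
  embedding above the 1e-4 candidate threshold while deleting any single
  module gene stays below it — i.e. the generator meets the detectability
  contract the screen is specified against.

What the generator does *not* emulate: doublets, ambient RNA, gene–gene
correlation beyond the group programs, realistic dropout curves, or any
particular published dataset. Passing tests therefore demonstrate that the
algorithms behave as specified under clean, planted structure — not that
real tissues will separate as cleanly.

Reference problem sizes used throughout the tests and the acceptance
script — 600 cells × 200 genes × 4 types (×2 conditions for the disease
screen), embedding dimension 64 — are chosen so the planted structure is
comfortably detectable while the whole suite runs in well under a minute
of compute per scenario.

## Numerical conventions and degenerate inputs

* Zero-total rows: zero weights under wa (no NaNs), zero rows preserved by
  normalization.
* kNN ties: lower cell index wins; k is clipped to n−1 with a warning.
* Annotation ties: the nearest neighbor among tied labels decides.
* ARI may be negative; it is clipped only inside S_bio.
* Chi-squared acceptance in kBET is strict (p > α).
* The candidate threshold is strict (score > 1e-4; equality is not a call).
* Floating-point contracts: aggregation agrees with a loop oracle to 1e-10;
  composite means and score = CS_new − CS_old identities hold to 1e-12.

## Known limitations

The shipped embedding provider is a deterministic string-hash unit-vector
generator: it makes the full pipeline runnable and testable offline, but
its vectors carry no biological information, so end-to-end biological
claims require a real embedding table as input. The adaptor is CPU-oriented
and small by design; it is not a route to atlas-scale training. The LISI
variant implemented is the simplified walk, which is not numerically
comparable to inverse-Simpson LISI values reported elsewhere.
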