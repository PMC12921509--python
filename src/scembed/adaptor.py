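"""Fine-tuning adaptor: a light feed-forward encoder over cell embeddings.

The adaptor maps aggregated cell embeddings through a small ReLU MLP and is
trained on a cell-label classification task with a combined objective

    L_total = L_classifier + lambda * L_contrastive,

where L_classifier is softmax cross-entropy on a linear head over the last
hidden layer, and L_contrastive is a supervised contrastive loss
(normalized-temperature cross-entropy over same-class positives within each
mini-batch) on the L2-normalized last hidden representation. The large
default weight lambda = 100 pushes same-label cells together in the latent
space, which is what downstream kNN annotation and the in-silico treatment
screen consume. The encoder output (pre-classifier hidden layer) is the
fine-tuned embedding; the classifier head is discarded downstream.

Everything is plain numpy with manually derived gradients and Adam, so a
fixed (data, config, seed) triple reproduces parameters and loss traces
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .data import CellEmbeddingMatrix, ValidationError
from .zeroshot import knn_annotate


@dataclass
class AdaptorConfig:
    """Hyper-parameters of the adaptor.

    lambda_contrastive weights the contrastive term (0 disables it);
    temperature scales the contrastive similarities; hidden_dims fixes the
    encoder width per layer (the last entry is the latent dimension).
    """

    input_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [256, 64])
    lambda_contrastive: float = 100.0
    temperature: float = 0.1
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_dims:
            raise ValidationError("hidden_dims must be nonempty")
        if self.lambda_contrastive < 0:
            raise ValidationError("lambda_contrastive must be >= 0")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


def _init_params(cfg: AdaptorConfig, n_classes: int, rng: np.random.Generator):
    dims = [cfg.input_dim] + list(cfg.hidden_dims) + [n_classes]
    params = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        params.append([W, np.zeros(d_out)])
    return params


def _forward(params, X):
    """Returns (activations per layer, logits). Hidden layers use ReLU."""
    acts = [X]
    h = X
    for W, b in params[:-1]:
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    W, b = params[-1]
    return acts, h @ W + b


def _softmax_ce(logits, y_idx):
    """Mean cross-entropy and gradient wrt logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), y_idx] + 1e-300))
    grad = p.copy()
    grad[np.arange(n), y_idx] -= 1.0
    return loss, grad / n


def _supcon(h, y_idx, temperature):
    """Supervised contrastive loss on L2-normalized h, with gradient wrt h.

    For each anchor i with at least one same-class positive in the batch,
    L_i = -mean_{p in P(i)} log( exp(z_i.z_p/T) / sum_{a != i} exp(z_i.z_a/T) );
    the loss is the mean over valid anchors. Anchors without positives
    contribute nothing.
    """
    n = h.shape[0]
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    z = h / norms
    S = (z @ z.T) / temperature
    off = ~np.eye(n, dtype=bool)
    pos = (y_idx[:, None] == y_idx[None, :]) & off
    n_pos = pos.sum(axis=1)
    valid = n_pos > 0
    if not valid.any():
        return 0.0, np.zeros_like(h)
    # row-wise log-softmax over a != i
    S_off = np.where(off, S, -np.inf)
    m = S_off.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(S_off - m).sum(axis=1))
    loss_rows = np.where(valid, -(np.where(pos, S, 0.0).sum(axis=1) / np.maximum(n_pos, 1) - lse), 0.0)
    n_valid = valid.sum()
    loss = loss_rows[valid].mean()
    # gradient wrt S: for valid anchor i, dL_i/dS_ia = softmax_ia - pos_ia/n_pos_i
    softmax = np.exp(S_off - lse[:, None])
    G = np.where(valid[:, None], softmax - pos / np.maximum(n_pos, 1)[:, None], 0.0)
    G[~off.astype(bool)] = 0.0
    G /= n_valid
    # S = z z^T / T  ->  dL/dz = (G + G^T) z / T
    gz = (G + G.T) @ z / temperature
    # through normalization z = h/||h||: dL/dh = (gz - (gz.z) z)/||h||
    gh = (gz - (gz * z).sum(axis=1, keepdims=True) * z) / norms
    return float(loss), gh


@dataclass
class TrainedAdaptor:
    """Fitted adaptor parameters plus the training record.

    ``loss_trace`` has one row per epoch with the mini-batch-averaged total,
    classifier, and contrastive components (the recorded total is exactly
    classifier + lambda * contrastive).
    """

    params: list
    classes: list[str]
    config: AdaptorConfig
    loss_trace: dict
    best_epoch: int

    @property
    def latent_dim(self) -> int:
        return self.config.hidden_dims[-1]

    def summary(self) -> str:
        tr = self.loss_trace
        lines = [
            "TrainedAdaptor",
            f"  architecture : {self.config.input_dim} -> "
            + " -> ".join(map(str, self.config.hidden_dims))
            + f" -> {len(self.classes)} classes (ReLU)",
            f"  lambda       : {self.config.lambda_contrastive}",
            f"  temperature  : {self.config.temperature}",
            f"  epochs       : {self.config.epochs} (best epoch {self.best_epoch})",
            f"  final losses : total={tr['total'][-1]:.4f} "
            f"classifier={tr['classifier'][-1]:.4f} "
            f"contrastive={tr['contrastive'][-1]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        """JSON checkpoint: config manifest + flat weight arrays."""
        blob = {
            "config": asdict(self.config),
            "classes": self.classes,
            "best_epoch": self.best_epoch,
            "loss_trace": {k: list(map(float, v)) for k, v in self.loss_trace.items()},
            "params": [[W.tolist(), b.tolist()] for W, b in self.params],
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "TrainedAdaptor":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            params=[[np.array(W), np.array(b)] for W, b in blob["params"]],
            classes=list(blob["classes"]),
            config=AdaptorConfig(**blob["config"]),
            loss_trace=blob["loss_trace"],
            best_epoch=blob["best_epoch"],
        )


class ContrastiveAdaptor:
    """Model object: build from embeddings + labels, ``fit()`` to train."""

    def __init__(self, emb: CellEmbeddingMatrix, labels, config: AdaptorConfig | None = None):
        self.emb = emb
        self.labels = [str(l) for l in labels]
        if len(self.labels) != emb.n_cells:
            raise ValidationError("one label per cell required")
        self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValidationError("need >= 2 classes")
        counts = {c: self.labels.count(c) for c in self.classes}
        singletons = [c for c, n in counts.items() if n < 2]
        if singletons:
            raise ValidationError(
                f"class(es) with a single cell (no contrastive positives): {singletons}"
            )
        self.config = config or AdaptorConfig(input_dim=emb.dim)
        if self.config.input_dim != emb.dim:
            raise ValidationError(
                f"config input_dim {self.config.input_dim} != embedding dim {emb.dim}"
            )

    def fit(self) -> TrainedAdaptor:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        X = self.emb.vectors
        y = np.array([self.classes.index(l) for l in self.labels])
        n = X.shape[0]

        # stratified train/validation split for best-epoch selection
        val_idx = []
        if cfg.val_fraction > 0:
            for c in range(len(self.classes)):
                members = np.flatnonzero(y == c)
                members = members[rng.permutation(members.size)]
                n_val = int(np.floor(members.size * cfg.val_fraction))
                val_idx.extend(members[:n_val])
        val_idx = np.array(sorted(val_idx), dtype=int)
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        tr_idx = np.flatnonzero(train_mask)

        params = _init_params(cfg, len(self.classes), rng)
        mom = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        trace = {"total": [], "classifier": [], "contrastive": []}
        best_val, best_params, best_epoch = np.inf, None, -1

        for epoch in range(cfg.epochs):
            order = tr_idx[rng.permutation(tr_idx.size)]
            ep_tot, ep_cls, ep_con, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                if batch.size < 2:
                    continue
                Xb, yb = X[batch], y[batch]
                acts, logits = _forward(params, Xb)
                h = acts[-1]
                cls_loss, dlogits = _softmax_ce(logits, yb)
                if cfg.lambda_contrastive > 0:
                    con_loss, dh_con = _supcon(h, yb, cfg.temperature)
                else:
                    con_loss, dh_con = 0.0, 0.0
                total = cls_loss + cfg.lambda_contrastive * con_loss
                if not np.isfinite(total):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}: classifier={cls_loss}, "
                        f"contrastive={con_loss}; try a lower learning rate"
                    )
                # backward
                grads = [[None, None] for _ in params]
                W_out, _ = params[-1]
                grads[-1][0] = h.T @ dlogits
                grads[-1][1] = dlogits.sum(axis=0)
                dh = dlogits @ W_out.T + cfg.lambda_contrastive * dh_con
                for li in range(len(params) - 2, -1, -1):
                    dh = dh * (acts[li + 1] > 0)
                    grads[li][0] = acts[li].T @ dh
                    grads[li][1] = dh.sum(axis=0)
                    if li > 0:
                        dh = dh @ params[li][0].T
                # Adam update
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for p, m, v, g in zip(params, mom, vel, grads):
                    for j in range(2):
                        m[j] = beta1 * m[j] + (1 - beta1) * g[j]
                        v[j] = beta2 * v[j] + (1 - beta2) * g[j] ** 2
                        p[j] -= lr_t * m[j] / (np.sqrt(v[j]) + eps)
                ep_tot += total
                ep_cls += cls_loss
                ep_con += con_loss
                n_batches += 1
            trace["total"].append(ep_tot / max(n_batches, 1))
            trace["classifier"].append(ep_cls / max(n_batches, 1))
            trace["contrastive"].append(ep_con / max(n_batches, 1))

            if val_idx.size:
                _, vlogits = _forward(params, X[val_idx])
                vloss, _ = _softmax_ce(vlogits, y[val_idx])
                if vloss < best_val:
                    best_val = vloss
                    best_params = [[W.copy(), b.copy()] for W, b in params]
                    best_epoch = epoch

        if best_params is not None:
            params = best_params
        else:
            best_epoch = cfg.epochs - 1
        return TrainedAdaptor(
            params=params, classes=self.classes, config=cfg,
            loss_trace=trace, best_epoch=best_epoch,
        )


def train_adaptor(emb: CellEmbeddingMatrix, labels, cfg: AdaptorConfig | None = None) -> TrainedAdaptor:
    """Convenience wrapper: ``ContrastiveAdaptor(emb, labels, cfg).fit()``."""
    return ContrastiveAdaptor(emb, labels, cfg).fit()


def adaptor_embed(model: TrainedAdaptor, emb: CellEmbeddingMatrix) -> CellEmbeddingMatrix:
    """Deterministic forward pass through the encoder (head excluded)."""
    if emb.dim != model.config.input_dim:
        raise ValidationError(
            f"embedding dim {emb.dim} != model input dim {model.config.input_dim}"
        )
    acts, _ = _forward(model.params, emb.vectors)
    return CellEmbeddingMatrix(list(emb.cell_ids), acts[-1])


def annotate_finetuned(
    model: TrainedAdaptor,
    train_emb: CellEmbeddingMatrix,
    train_labels,
    test_emb: CellEmbeddingMatrix,
    k: int = 10,
):
    """kNN annotation in the fine-tuned latent space (k = 10 by default)."""
    z_train = adaptor_embed(model, train_emb)
    z_test = adaptor_embed(model, test_emb)
    return knn_annotate(z_train, train_labels, z_test, k=k)
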