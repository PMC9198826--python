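"""Modified transformer encoder for multilabel prescription recommendation.

The classifier maps one patient's fixed-size embedding matrix to a vector of
per-category probabilities.  Architecture: sinusoidal positional encoding,
then two identical cascaded encoders (multihead self-attention with 4 heads
of dimension 8, residual + layer normalisation at the model width,
position-wise feedforward, residual + layer normalisation), then a masked
mean pooling over token positions and a classification head (linear ->
feedforward -> 128-unit hidden layer with dropout and normalisation ->
sigmoid output, one unit per first-category label).  A prescription is
decoded from the probabilities with a threshold.

Training minimises the mean per-label binary log loss with a small L2
penalty, Adam updates, and global gradient-norm clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from statistics import mode

import numpy as np
from sklearn.model_selection import KFold

from ._autodiff import Tensor, exp, log, relu
from . import nn
from .embed import EmbeddingMatrix

__all__ = ["TransformerConfig", "TrainConfig", "PrescriptionTransformer",
           "decode", "train_model", "tune_hyperparameters", "TrainingDiverged"]


@dataclass(frozen=True)
class TransformerConfig:
    n_encoders: int = 2
    multi_heads: int = 4
    head_dim: int = 8
    model_dim: int = 100          # equals the embedding vector_size
    ffn_dim: int = 2048
    hidden_dim: int = 128
    hidden_dropout: float = 0.4740
    input_dropout: float = 0.4410  # dropout on the input embedding layer
    n_labels: int = 819
    max_num_tokens: int = 759
    decode_threshold: float = 0.5
    pooling: str = "mean"          # "mean" (masked) or "eos" (learned token)

    def __post_init__(self):
        for name in ("n_encoders", "multi_heads", "head_dim", "model_dim",
                     "ffn_dim", "hidden_dim", "n_labels", "max_num_tokens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.hidden_dropout < 1.0:
            raise ValueError("hidden_dropout must be in [0,1)")
        if not 0.0 < self.decode_threshold < 1.0:
            raise ValueError("decode_threshold must be in (0,1)")

    @classmethod
    def desk_scale(cls, n_labels: int, **kw) -> "TransformerConfig":
        """Reduced-dimension preset so recovery experiments run on one CPU."""
        base = dict(model_dim=32, ffn_dim=128, hidden_dim=32, head_dim=8,
                    max_num_tokens=64, hidden_dropout=0.1, input_dropout=0.1,
                    n_labels=n_labels)
        base.update(kw)
        return cls(**base)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-3
    reference_learning_rate: float = 0.4375  # previously reported tuned value
    use_reference_learning_rate: bool = False
    l2_rate: float = 0.000001566
    grad_clip: float = 0.1245
    epochs: int = 40
    seed: int = 0
    cv_folds: int = 10
    holdout_frac: float = 0.10

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l2_rate < 0:
            raise ValueError("l2_rate must be >= 0")
        if not 0.0 < self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must be in (0,1)")

    @property
    def effective_learning_rate(self) -> float:
        return self.reference_learning_rate if self.use_reference_learning_rate \
            else self.learning_rate

    @classmethod
    def desk_scale(cls, **kw) -> "TrainConfig":
        """Reduced-scale preset: smaller batches give enough optimizer steps
        on cohorts of a few hundred patients; step size raised accordingly."""
        base = dict(batch_size=32, learning_rate=3e-3, epochs=60)
        base.update(kw)
        return cls(**base)


class TrainingDiverged(RuntimeError):
    pass


class _EncoderLayer(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.attn = nn.MultiheadSelfAttention(cfg.model_dim, cfg.multi_heads,
                                              cfg.head_dim, rng)
        self.ln1 = nn.LayerNorm(cfg.model_dim)
        self.ffn = nn.PositionwiseFFN(cfg.model_dim, cfg.ffn_dim, rng)
        self.ln2 = nn.LayerNorm(cfg.model_dim)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.attn(x, mask))
        return self.ln2(x + self.ffn(x))


class PrescriptionTransformer(nn.Module):
    def __init__(self, cfg: TransformerConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.pe = nn.sinusoidal_positional_encoding(cfg.max_num_tokens, cfg.model_dim)
        self.encoders = [_EncoderLayer(cfg, rng) for _ in range(cfg.n_encoders)]
        self.eos = Tensor(rng.normal(0, 0.02, size=cfg.model_dim), requires_grad=True)
        self.linear = nn.Linear(cfg.model_dim, cfg.model_dim, rng)
        self.ff = nn.Linear(cfg.model_dim, cfg.ffn_dim, rng)
        self.hidden = nn.Linear(cfg.ffn_dim, cfg.hidden_dim, rng)
        self.hidden_norm = nn.LayerNorm(cfg.hidden_dim)
        self.hidden_drop = nn.Dropout(cfg.hidden_dropout)
        self.input_drop = nn.Dropout(cfg.input_dropout)
        self.out = nn.Linear(cfg.hidden_dim, cfg.n_labels, rng)

    # -- forward -----------------------------------------------------------
    def _check(self, X: np.ndarray) -> None:
        if X.shape[-2:] != (self.cfg.max_num_tokens, self.cfg.model_dim):
            raise ValueError(
                f"expected input shaped (..., {self.cfg.max_num_tokens}, "
                f"{self.cfg.model_dim}), got {X.shape}"
            )

    def logits(self, X: np.ndarray, mask: np.ndarray,
               train_rng: np.random.Generator | None = None) -> Tensor:
        """X: (B, T, D) embedding matrices; mask: (B, T) validity flags.

        `train_rng` activates dropout; inference passes None.
        """
        self._check(X)
        maskf = mask.astype(np.float64)[:, :, None]
        x = Tensor((X + self.pe[None, : X.shape[1], :]) * maskf)
        x = self.input_drop(x, train_rng)
        for enc in self.encoders:
            x = enc(x, mask)
        if self.cfg.pooling == "eos":
            # weight positions by similarity to a learned end-of-sequence
            # embedding (masked softmax), an attention-style readout
            scores = (x * self.eos.reshape(1, 1, -1)).sum(axis=-1)
            bias = Tensor(np.where(mask, 0.0, -1e9))
            w = nn.softmax(scores + bias, axis=-1)
            pooled = (x * w.reshape(*w.shape, 1)).sum(axis=1)
        else:  # masked mean; empty records pool to the zero vector
            counts = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
            pooled = (x * Tensor(maskf)).sum(axis=1) / Tensor(counts)
        h = relu(self.ff(relu(self.linear(pooled))))
        h = self.hidden_norm(self.hidden_drop(relu(self.hidden(h)), train_rng))
        return self.out(h)

    def forward(self, x: EmbeddingMatrix) -> np.ndarray:
        """Probabilities for one embedding matrix (inference mode)."""
        probs = self.predict_proba(x.values[None], x.mask[None])
        return probs[0]

    def predict_proba(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        z = self.logits(X, mask).data
        p = 1.0 / (1.0 + np.exp(-z))
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    def predict_sets(self, X: np.ndarray, mask: np.ndarray,
                     threshold: float | None = None) -> list[set[int]]:
        thr = self.cfg.decode_threshold if threshold is None else threshold
        probs = self.predict_proba(X, mask)
        return [decode(p, thr) for p in probs]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PrescriptionTransformer":
        path = Path(path)
        cfg = TransformerConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def decode(probs: np.ndarray, threshold: float) -> set[int]:
    """Label indices whose probability reaches the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    return set(np.flatnonzero(np.asarray(probs) >= threshold).tolist())


def _bce_from_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy, softplus(z) - z*y."""
    absz = relu(z) + relu(-z)
    softplus = relu(z) + log(exp(-absz) + 1.0)
    return (softplus - z * Tensor(y)).mean()


def _stack_dataset(dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([em.values for em, _ in dataset])
    M = np.stack([em.mask for em, _ in dataset])
    Y = np.stack([np.asarray(y, dtype=np.float64) for _, y in dataset])
    return X, M, Y


def train_model(
    train_set: list[tuple[EmbeddingMatrix, np.ndarray]],
    cfg: TransformerConfig,
    tcfg: TrainConfig,
    validation: list[tuple[EmbeddingMatrix, np.ndarray]] | None = None,
) -> tuple[PrescriptionTransformer, list[dict]]:
    """Supervised training; returns the model and a per-epoch loss trace."""
    if not train_set:
        raise ValueError("training set is empty")
    X, M, Y = _stack_dataset(train_set)
    if Y.shape[1] != cfg.n_labels:
        raise ValueError(f"label vectors have length {Y.shape[1]}, expected {cfg.n_labels}")
    model = PrescriptionTransformer(cfg, seed=tcfg.seed)
    params = model.parameters()
    opt = nn.Adam(params, lr=tcfg.effective_learning_rate, weight_decay=tcfg.l2_rate)
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 11]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 13]))
    history: list[dict] = []
    n = len(train_set)
    for epoch in range(tcfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, tcfg.batch_size):
            idx = perm[lo : lo + tcfg.batch_size]
            model.zero_grad()
            z = model.logits(X[idx], M[idx], train_rng=drop_rng)
            loss = _bce_from_logits(z, Y[idx])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {lo // tcfg.batch_size}"
                )
            loss.backward()
            nn.clip_grad_norm(params, tcfg.grad_clip)
            opt.step()
            losses.append(lval)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if validation:
            entry["val_loss"] = float(log_loss_on(model, validation))
        history.append(entry)
    return model, history


def log_loss_on(model: PrescriptionTransformer,
                dataset: list[tuple[EmbeddingMatrix, np.ndarray]]) -> float:
    X, M, Y = _stack_dataset(dataset)
    z = model.logits(X, M)
    return float(_bce_from_logits(z, Y).data)


# -- grid-search tuning ----------------------------------------------------

_TRANSFORMER_FIELDS = set(TransformerConfig.__dataclass_fields__)
_TRAIN_FIELDS = set(TrainConfig.__dataclass_fields__)


def tune_hyperparameters(
    dataset: list[tuple[EmbeddingMatrix, np.ndarray]],
    grid: dict[str, list],
    cfg: TransformerConfig,
    tcfg: TrainConfig,
) -> tuple[TransformerConfig, TrainConfig, list[dict]]:
    """K-fold cross-validated grid search with per-fold winner averaging.

    Each fold independently picks the grid point with minimal validation log
    loss; the returned configuration averages the numeric winners across
    folds (majority vote for categorical parameters).  This per-fold
    averaging protocol is unusual but is the tuning procedure this pipeline
    specifies; with a single grid point it degenerates to that point.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be a non-empty cartesian product")
    unknown = set(grid) - _TRANSFORMER_FIELDS - _TRAIN_FIELDS
    if unknown:
        raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")
    keys = sorted(grid)
    points: list[dict] = [{}]
    for k in keys:
        points = [{**p, k: v} for p in points for v in grid[k]]
    kf = KFold(n_splits=tcfg.cv_folds, shuffle=True, random_state=tcfg.seed)
    fold_winners: list[dict] = []
    trace: list[dict] = []
    for fold, (tr, va) in enumerate(kf.split(dataset)):
        tr_set = [dataset[i] for i in tr]
        va_set = [dataset[i] for i in va]
        best, best_loss = None, np.inf
        for point in points:
            c = replace(cfg, **{k: v for k, v in point.items() if k in _TRANSFORMER_FIELDS})
            t = replace(tcfg, **{k: v for k, v in point.items() if k in _TRAIN_FIELDS})
            m, _ = train_model(tr_set, c, t)
            loss = log_loss_on(m, va_set)
            trace.append({"fold": fold, **point, "val_loss": loss})
            if loss < best_loss:
                best, best_loss = point, loss
        fold_winners.append(best)
    merged: dict = {}
    for k in keys:
        vals = [w[k] for w in fold_winners]
        if all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in vals):
            avg = float(np.mean(vals))
            if all(isinstance(v, int) for v in vals):
                avg = int(round(avg))
            merged[k] = avg
        else:
            merged[k] = mode(vals)
    out_cfg = replace(cfg, **{k: v for k, v in merged.items() if k in _TRANSFORMER_FIELDS})
    out_tcfg = replace(tcfg, **{k: v for k, v in merged.items() if k in _TRAIN_FIELDS})
    return out_cfg, out_tcfg, trace
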