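"""LSTM-based generative adversarial augmentation of training embeddings.

The generator receives an original embedding matrix with i.i.d. Gaussian
noise injected into its real token rows and produces a noise-added sample of
identical shape and mask (padded rows stay zero); the discriminator scores a
sample as original vs generated.  The two are trained in alternation — the
discriminator on balanced 2x``batch_size`` batches until its binary
cross-entropy plateaus, then the generator against the frozen discriminator
until the adversarial loss plateaus — one such pair of phases forming an
epoch, until the discriminator hovers at chance (the operational Nash
criterion) or a hard epoch cap.  After training, each original sample yields
one generated sample inheriting its label vector, doubling the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, exp, log, relu
from . import nn
from .embed import EmbeddingMatrix

__all__ = ["GanConfig", "Generator", "Discriminator", "train_gan",
           "augment_dataset", "AugmentedSample", "GanDiverged"]


@dataclass(frozen=True)
class GanConfig:
    lstm_size: int = 279
    disc_resnorm_width: int = 100
    disc_fc_width: int = 256
    batch_size: int = 500
    max_epochs: int = 30
    max_inner_steps: int = 40      # cap on one D- or G-phase
    patience: int = 5
    plateau_rtol: float = 1e-3
    equilibrium_band: tuple[float, float] = (0.45, 0.55)
    noise_sigma: float = 0.1
    learning_rate: float = 1e-3
    conditional: bool = False      # reserved: label-conditioned generation
    seed: int = 0

    def __post_init__(self):
        for name in ("lstm_size", "disc_resnorm_width", "disc_fc_width",
                     "batch_size", "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def desk_scale(cls, **kw) -> "GanConfig":
        base = dict(lstm_size=32, disc_resnorm_width=32, disc_fc_width=32,
                    batch_size=64, max_epochs=12, max_inner_steps=15)
        base.update(kw)
        return cls(**base)


class GanDiverged(RuntimeError):
    pass


class Generator(nn.Module):
    """Two stacked LSTMs (width ``lstm_size``), each with residual + layer
    normalisation, bracketed by linear projections between the embedding
    width and the LSTM width.  The output is a residual perturbation of the
    input, so an identity-initialised (zeroed) output projection with zero
    noise reproduces the input exactly."""

    def __init__(self, model_dim: int, cfg: GanConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 21]))
        self.cfg = cfg
        self.in_proj = nn.Linear(model_dim, cfg.lstm_size, rng)
        self.lstm1 = nn.LSTM(cfg.lstm_size, cfg.lstm_size, rng)
        self.ln1 = nn.LayerNorm(cfg.lstm_size)
        self.lstm2 = nn.LSTM(cfg.lstm_size, cfg.lstm_size, rng)
        self.ln2 = nn.LayerNorm(cfg.lstm_size)
        self.out_proj = nn.Linear(cfg.lstm_size, model_dim, rng)
        # start near the identity map: early fakes are small perturbations
        self.out_proj.W.data *= 0.1

    def _forward(self, x: Tensor, maskf: np.ndarray) -> Tensor:
        h = self.in_proj(x)
        h = self.ln1(h + self.lstm1(h))
        h = self.ln2(h + self.lstm2(h))
        delta = self.out_proj(h)
        return (x + delta) * Tensor(maskf)

    def generate_batch(self, X: np.ndarray, mask: np.ndarray,
                       rng: np.random.Generator) -> Tensor:
        maskf = mask.astype(np.float64)[:, :, None]
        noise = rng.normal(0.0, self.cfg.noise_sigma, size=X.shape) * maskf
        return self._forward(Tensor(X + noise), maskf)

    def generate(self, x: EmbeddingMatrix, noise_seed: int) -> EmbeddingMatrix:
        """One noise-added sample for one original; same shape and mask."""
        rng = np.random.default_rng(noise_seed)
        out = self.generate_batch(x.values[None], x.mask[None], rng)
        return EmbeddingMatrix(values=out.data[0].copy(), mask=x.mask.copy())


class Discriminator(nn.Module):
    """LSTM (width ``lstm_size``) -> residual + normalisation block at
    ``disc_resnorm_width`` -> fully connected ``disc_fc_width`` -> sigmoid
    scalar (probability the sample is an original)."""

    def __init__(self, model_dim: int, cfg: GanConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 22]))
        self.lstm = nn.LSTM(model_dim, cfg.lstm_size, rng)
        self.proj = nn.Linear(cfg.lstm_size, cfg.disc_resnorm_width, rng)
        self.res = nn.Linear(cfg.disc_resnorm_width, cfg.disc_resnorm_width, rng)
        self.ln = nn.LayerNorm(cfg.disc_resnorm_width)
        self.fc = nn.Linear(cfg.disc_resnorm_width, cfg.disc_fc_width, rng)
        self.out = nn.Linear(cfg.disc_fc_width, 1, rng)

    def logits(self, x: Tensor, mask: np.ndarray) -> Tensor:
        h = self.lstm(x)  # (B, T, H)
        # read the hidden state at each sample's last real token
        last = np.maximum(mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1), 0)
        last = np.where(mask.any(axis=1), last, 0)
        h = h[np.arange(h.shape[0]), last]
        p = self.proj(h)
        p = self.ln(p + relu(self.res(p)))
        return self.out(relu(self.fc(p))).reshape(-1)

    def discriminate(self, x: EmbeddingMatrix) -> float:
        z = self.logits(Tensor(x.values[None]), x.mask[None])
        return float(1.0 / (1.0 + np.exp(-z.data[0])))

    def predict_proba(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        z = self.logits(Tensor(X), mask).data
        return 1.0 / (1.0 + np.exp(-z))


def _bce(z: Tensor, y: np.ndarray) -> Tensor:
    absz = relu(z) + relu(-z)
    softplus = relu(z) + log(exp(-absz) + 1.0)
    return (softplus - z * Tensor(y)).mean()


class _Plateau:
    """Stop signal: best value fails to improve (in `direction`) by a
    relative tolerance for `patience` consecutive evaluations."""

    def __init__(self, patience: int, rtol: float, direction: str = "min"):
        self.patience = patience
        self.rtol = rtol
        self.sign = 1.0 if direction == "min" else -1.0
        self.best = np.inf
        self.stale = 0

    def update(self, value: float) -> bool:
        v = self.sign * value
        if v < self.best * (1.0 - np.sign(self.best) * self.rtol):
            self.best = v
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    """Endless shuffled index batches that wrap around the dataset."""
    while True:
        perm = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = perm[lo : lo + batch_size]
            if len(idx) < batch_size:  # wrap to keep batches full
                idx = np.concatenate([idx, perm[: batch_size - len(idx)]])
            yield idx


def train_gan(
    originals: list[EmbeddingMatrix],
    cfg: GanConfig,
) -> tuple[Generator, Discriminator, list[dict]]:
    """Alternating adversarial training; returns (G, D, per-epoch history).

    Each history entry records the discriminator-phase and generator-phase
    loss segments and the end-of-epoch discriminator balanced accuracy used
    by the equilibrium stop rule.
    """
    if not originals:
        raise ValueError("no original samples")
    X = np.stack([em.values for em in originals])
    M = np.stack([em.mask for em in originals])
    model_dim = X.shape[2]
    G = Generator(model_dim, cfg)
    D = Discriminator(model_dim, cfg)
    g_opt = nn.Adam(G.parameters(), lr=cfg.learning_rate)
    d_opt = nn.Adam(D.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    batch_size = min(cfg.batch_size, len(originals))
    batches = _batches(len(originals), batch_size, rng)
    history: list[dict] = []
    in_band = 0
    eq_state: tuple[dict, dict, int] | None = None
    for epoch in range(cfg.max_epochs):
        # -- discriminator phase ------------------------------------------
        d_losses: list[float] = []
        plateau = _Plateau(cfg.patience, cfg.plateau_rtol, "min")
        for _ in range(cfg.max_inner_steps):
            idx = next(batches)
            fakes = G.generate_batch(X[idx], M[idx], rng).detach()
            xb = Tensor(np.concatenate([X[idx], fakes.data]))
            mb = np.concatenate([M[idx], M[idx]])
            yb = np.concatenate([np.ones(len(idx)), np.zeros(len(idx))])
            D.zero_grad()
            loss = _bce(D.logits(xb, mb), yb)
            if not np.isfinite(loss.data):
                raise GanDiverged(f"discriminator loss non-finite at epoch {epoch}")
            loss.backward()
            d_opt.step()
            d_losses.append(float(loss.data))
            if plateau.update(float(loss.data)):
                break
        # -- generator phase (D frozen) ------------------------------------
        g_losses: list[float] = []
        adv_trace: list[float] = []
        plateau = _Plateau(cfg.patience, cfg.plateau_rtol, "max")
        for _ in range(cfg.max_inner_steps):
            idx = next(batches)
            G.zero_grad()
            fakes = G.generate_batch(X[idx], M[idx], rng)
            z = D.logits(fakes, M[idx])
            # non-saturating generator objective: make D call fakes original
            g_loss = _bce(z, np.ones(len(idx)))
            if not np.isfinite(g_loss.data):
                raise GanDiverged(f"generator loss non-finite at epoch {epoch}")
            g_loss.backward()
            for p in D.parameters():  # frozen discriminator
                p.grad = None
            g_opt.step()
            g_losses.append(float(g_loss.data))
            # D's own loss on fakes rises as G improves; plateau of that
            # increase ends the phase
            adv = float(_bce(z.detach(), np.zeros(len(idx))).data)
            adv_trace.append(adv)
            if plateau.update(adv):
                break
        # -- equilibrium check ---------------------------------------------
        idx = next(batches)
        fakes = G.generate_batch(X[idx], M[idx], rng).detach()
        p_real = D.predict_proba(X[idx], M[idx])
        p_fake = D.predict_proba(fakes.data, M[idx])
        balacc = 0.5 * ((p_real >= 0.5).mean() + (p_fake < 0.5).mean())
        history.append({
            "epoch": epoch, "d_losses": d_losses, "g_losses": g_losses,
            "d_loss_on_fakes": adv_trace, "d_balanced_accuracy": float(balacc),
        })
        lo, hi = cfg.equilibrium_band
        if lo <= balacc <= hi:
            # the alternation keeps oscillating after passing through
            # equilibrium; remember the most recent equilibrium state so the
            # hard epoch cap cannot strand us at an off-balance phase
            eq_state = (G.state_dict(), D.state_dict(), epoch)
            in_band += 1
        else:
            in_band = 0
        if in_band >= cfg.patience:
            break
    if eq_state is not None:
        g_state, d_state, eq_epoch = eq_state
        G.load_state_dict(g_state)
        D.load_state_dict(d_state)
        history[-1]["equilibrium_epoch"] = eq_epoch
    return G, D, history


@dataclass
class AugmentedSample:
    x: EmbeddingMatrix
    y: np.ndarray
    origin: str  # "original" | "generated"


def augment_dataset(
    originals: list[tuple[EmbeddingMatrix, np.ndarray]],
    G: Generator,
    seed: int = 0,
) -> list[AugmentedSample]:
    """One generated sample per original, inheriting the original's label
    vector; the originals pass through untouched.  Output size is 2N."""
    out: list[AugmentedSample] = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    for em, y in originals:
        out.append(AugmentedSample(x=em, y=y, origin="original"))
    for em, y in originals:
        fake = G.generate(em, noise_seed=int(rng.integers(2**31)))
        out.append(AugmentedSample(x=fake, y=np.array(y, copy=True), origin="generated"))
    return out
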