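"""Wasserstein-GAN tabular augmentation of (features, LPN) rows.

A small generator network maps latent Gaussian noise to synthetic rows;
a critic network scores rows, constrained to (approximately) Lipschitz
functions by weight clipping.  Training alternates ``n_critic`` critic
ascent steps on mean[D(x)] - mean[D(G(z))] with one generator descent
step on -mean[D(G(z))], using Adam with beta1 = 0, beta2 = 0.9,
generator learning rate 1e-4 and critic learning rate 2e-4, batch size
16, for up to 200 epochs.  The critic's real-minus-fake mean score is
the empirical surrogate of the Wasserstein distance between the real and
generated distributions.

Rows are z-scored per column on the training statistics before training
and the transform is inverted on generation.  Both networks are plain
fully connected numpy MLPs with leaky-rectifier hidden activations and
hand-written backpropagation — small enough that an autodiff framework
buys nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ricelpn.synth import ParameterError


class TrainingDataError(ValueError):
    """Too few rows to train the adversarial pair."""


class DivergenceError(RuntimeError):
    """Non-finite loss encountered during training."""


class ContractError(ValueError):
    """Shape/feature-count mismatch between real and synthetic data."""


@dataclass(frozen=True)
class WganConfig:
    latent_dim: int = 16
    batch_size: int = 16
    max_epochs: int = 200
    gen_lr: float = 1e-4
    critic_lr: float = 2e-4
    adam_beta1: float = 0.0
    adam_beta2: float = 0.9
    n_critic: int = 5
    clip_value: float = 0.01
    gen_hidden: tuple[int, ...] = (64, 64)
    critic_hidden: tuple[int, ...] = (64, 64)
    leak: float = 0.2
    clip_output: bool = True  # clamp generated rows to training range +/- 0.5*range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gen_lr <= 0 or self.critic_lr <= 0:
            raise ParameterError("learning rates must be positive")
        if self.n_critic < 1:
            raise ParameterError("n_critic must be >= 1")
        if self.clip_value <= 0:
            raise ParameterError("clip_value must be positive")


class _Mlp:
    """Fully connected net, leaky-ReLU hidden layers, linear output."""

    def __init__(self, sizes: list[int], leak: float, rng: np.random.Generator):
        self.leak = leak
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = math.sqrt(2.0 / fan_in)  # He initialization
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._cache: list[np.ndarray] = []

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = [x]
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if i == last else np.where(z > 0, z, self.leak * z)
            self._cache.append(h)
        return h

    def backward(self, grad_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of a scalar loss w.r.t. params and the input batch.

        Must follow a forward() call on the same batch.
        """
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            h_out = self._cache[i + 1]
            if i != last:  # undo leaky-ReLU using the cached activation sign
                g = g * np.where(h_out > 0, 1.0, self.leak)
            h_in = self._cache[i]
            gW[i] = h_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW + gb, g


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class GeneratorModel:
    """Trained generator plus the de-standardization and clipping state."""

    net: _Mlp
    latent_dim: int
    feature_names: list[str]
    col_mean: np.ndarray
    col_std: np.ndarray
    clip_lo: np.ndarray | None
    clip_hi: np.ndarray | None
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class CriticModel:
    net: _Mlp
    clip_value: float

    def max_abs_weight(self) -> float:
        return max(float(np.max(np.abs(p))) for p in self.net.params)


@dataclass
class AugmentedDataset:
    """Real training rows plus generated rows, flagged by origin."""

    rows: pd.DataFrame  # features + target columns
    origin: pd.Series  # "real" | "synthetic", aligned with rows


def train_wgan(
    train_rows: pd.DataFrame | np.ndarray,
    cfg: WganConfig = WganConfig(),
    return_critic: bool = False,
    weight_callback=None,
):
    """Train the adversarial pair on the (training-partition) rows.

    ``train_rows`` holds the selected features and the target jointly; the
    generator learns their joint distribution.  Returns the GeneratorModel
    (and the CriticModel when ``return_critic``).  ``weight_callback``, if
    given, is invoked with the critic after every critic update (used by
    tests to assert the clipping contract).
    """
    if isinstance(train_rows, pd.DataFrame):
        names = list(train_rows.columns)
        X = train_rows.to_numpy(dtype=float)
    else:
        X = np.asarray(train_rows, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"col{i}" for i in range(X.shape[1])]
    n, dim = X.shape
    if n < 2 * cfg.batch_size:
        raise TrainingDataError(f"need >= {2 * cfg.batch_size} rows, got {n}")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    Z = (X - mean) / std

    rng = np.random.default_rng(cfg.seed)
    gen = _Mlp([cfg.latent_dim, *cfg.gen_hidden, dim], cfg.leak, rng)
    critic = _Mlp([dim, *cfg.critic_hidden, 1], cfg.leak, rng)
    opt_g = _Adam(gen.params, cfg.gen_lr, cfg.adam_beta1, cfg.adam_beta2)
    opt_c = _Adam(critic.params, cfg.critic_lr, cfg.adam_beta1, cfg.adam_beta2)
    critic_model = CriticModel(net=critic, clip_value=cfg.clip_value)

    bs = cfg.batch_size
    steps_per_epoch = max(1, n // bs)
    history = []
    for epoch in range(cfg.max_epochs):
        g_losses, c_objs = [], []
        for _ in range(steps_per_epoch):
            for _ in range(cfg.n_critic):
                real = Z[rng.integers(0, n, size=bs)]
                noise = rng.standard_normal((bs, cfg.latent_dim))
                fake = gen.forward(noise)
                scores = critic.forward(np.vstack([real, fake]))
                c_obj = float(scores[:bs].mean() - scores[bs:].mean())
                if not math.isfinite(c_obj):
                    raise DivergenceError(f"non-finite critic objective at epoch {epoch}")
                # minimize the negated objective
                grad = np.vstack([np.full((bs, 1), -1.0 / bs), np.full((bs, 1), 1.0 / bs)])
                grads, _ = critic.backward(grad)
                opt_c.step(critic.params, grads)
                for p in critic.params:
                    np.clip(p, -cfg.clip_value, cfg.clip_value, out=p)
                c_objs.append(c_obj)
                if weight_callback is not None:
                    weight_callback(critic_model)
            # generator step: minimize -mean D(G(z))
            noise = rng.standard_normal((bs, cfg.latent_dim))
            fake = gen.forward(noise)
            scores = critic.forward(fake)
            g_loss = float(-scores.mean())
            if not math.isfinite(g_loss):
                raise DivergenceError(f"non-finite generator loss at epoch {epoch}")
            _, grad_fake = critic.backward(np.full((bs, 1), -1.0 / bs))
            grads, _ = gen.backward(grad_fake)
            opt_g.step(gen.params, grads)
            g_losses.append(g_loss)
        history.append(
            {"epoch": epoch, "generator_loss": float(np.mean(g_losses)), "critic_objective": float(np.mean(c_objs))}
        )

    lo = hi = None
    if cfg.clip_output:
        xmin, xmax = X.min(axis=0), X.max(axis=0)
        rng_col = xmax - xmin
        lo, hi = xmin - 0.5 * rng_col, xmax + 0.5 * rng_col
    g_model = GeneratorModel(
        net=gen,
        latent_dim=cfg.latent_dim,
        feature_names=names,
        col_mean=mean,
        col_std=std,
        clip_lo=lo,
        clip_hi=hi,
        history=pd.DataFrame(history),
    )
    return (g_model, critic_model) if return_critic else g_model


def generate_samples(g: GeneratorModel, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw n synthetic rows; identical seed gives bit-identical rows."""
    if n < 0:
        raise ParameterError("n must be nonnegative")
    if n == 0:
        return pd.DataFrame(columns=g.feature_names)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, g.latent_dim))
    raw = g.net.forward(noise) * g.col_std + g.col_mean
    if g.clip_lo is not None:
        raw = np.clip(raw, g.clip_lo, g.clip_hi)
    return pd.DataFrame(raw, columns=g.feature_names)


def augment_dataset(
    train_rows: pd.DataFrame, g: GeneratorModel, n_synthetic: int, seed: int = 0
) -> AugmentedDataset:
    """Stack the real training rows with n generated rows."""
    synth = generate_samples(g, n_synthetic, seed=seed)
    synth.index = [f"G{i + 1:04d}" for i in range(len(synth))]
    rows = pd.concat([train_rows, synth[train_rows.columns]], axis=0)
    origin = pd.Series(
        ["real"] * len(train_rows) + ["synthetic"] * len(synth), index=rows.index, name="origin"
    )
    return AugmentedDataset(rows=rows, origin=origin)


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """Empirical 1-D Wasserstein distance (integral of |ECDF difference|)."""
    return float(stats.wasserstein_distance(np.asarray(a, float), np.asarray(b, float)))


def compare_distributions(real, synthetic) -> pd.DataFrame:
    """Per-feature diagnostics: means, s.d.s, KS statistic, Wasserstein-1."""
    real_df = pd.DataFrame(real)
    synth_df = pd.DataFrame(synthetic)
    if real_df.shape[1] != synth_df.shape[1]:
        raise ContractError(
            f"feature-count mismatch: {real_df.shape[1]} vs {synth_df.shape[1]}"
        )
    rows = []
    for i, col in enumerate(real_df.columns):
        a = real_df[col].to_numpy(float)
        b = synth_df.iloc[:, i].to_numpy(float)
        rows.append(
            {
                "feature": str(col),
                "real_mean": a.mean(),
                "synth_mean": b.mean(),
                "real_sd": a.std(ddof=1),
                "synth_sd": b.std(ddof=1),
                "ks_statistic": float(stats.ks_2samp(a, b).statistic),
                "wasserstein": wasserstein_1d(a, b),
            }
        )
    return pd.DataFrame(rows)
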