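"""Fully-connected variational autoencoder for fixed-length 1-D signals.

The network is small enough (input -> 128 -> 64 -> 2*latent on the encoder,
mirrored on the decoder, ReLU activations, identity outputs) that it is
implemented directly in numpy with hand-derived gradients and an Adam (or
plain SGD) update rule.  Training is fully deterministic under a fixed seed:
weight initialization, mini-batch shuffling and the reparameterization draws
all derive from one ``SeedSequence``.

The loss is the negative evidence lower bound

    L = MSE(x, x_hat) + beta * KL(q(z|x) || N(0, I)),

with the reconstruction term averaged over samples and batch and the KL term
summed over latent dimensions and averaged over the batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "VAEConfig",
    "LatentStats",
    "TrainingHistory",
    "VAE",
    "kl_divergence",
    "total_loss",
    "train",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class VAEConfig:
    input_dim: int = 90
    latent_dim: int = 20
    hidden_dims: tuple[int, int] = (128, 64)
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 400
    beta: float = 1.0
    seed: int = 0
    optimizer: str = "adam"  # "adam" | "sgd"
    early_stopping: bool = False
    patience: int = 50

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.latent_dim < 1:
            raise ValueError("input_dim and latent_dim must be positive")
        if len(self.hidden_dims) != 2:
            raise ValueError("exactly two hidden layer widths are expected")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass(frozen=True)
class LatentStats:
    """Gaussian posterior parameters: mean and log-variance, per latent dim."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        log_var = np.asarray(self.log_var, dtype=float)
        if mu.shape != log_var.shape:
            raise ValueError("mu and log_var must have equal shapes")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
            raise ValueError("latent statistics must be finite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "log_var", log_var)

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class TrainingHistory:
    total: list[float] = field(default_factory=list)
    recon: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    val_total: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.total)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class VAE:
    """MLP encoder/decoder pair with explicit parameter arrays.

    Parameters live in ``self.params`` as a flat dict of float64 arrays so
    that checkpoints serialize to an ``.npz`` container and the optimizer can
    iterate over them generically.
    """

    PARAM_NAMES = ("We1", "be1", "We2", "be2", "We3", "be3", "Wd1", "bd1", "Wd2", "bd2", "Wd3", "bd3")

    def __init__(self, config: VAEConfig, init_rng: np.random.Generator | None = None):
        self.config = config
        h1, h2 = config.hidden_dims
        d, L = config.input_dim, config.latent_dim
        if init_rng is None:
            init_rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        shapes = {
            "We1": (d, h1), "be1": (h1,),
            "We2": (h1, h2), "be2": (h2,),
            "We3": (h2, 2 * L), "be3": (2 * L,),
            "Wd1": (L, h2), "bd1": (h2,),
            "Wd2": (h2, h1), "bd2": (h1,),
            "Wd3": (h1, d), "bd3": (d,),
        }
        self.params: dict[str, np.ndarray] = {}
        for name, shape in shapes.items():
            if name.startswith("W"):
                fan_in = shape[0]
                # He initialization suits the ReLU hidden layers
                self.params[name] = init_rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
            else:
                self.params[name] = np.zeros(shape)

    # ---------------------------------------------------------------- forward

    def encode(self, x: np.ndarray) -> LatentStats:
        """Map signals to posterior (mu, log_var); accepts one signal or a batch."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x2 = np.atleast_2d(x)
        if x2.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected input dimension {self.config.input_dim}, got {x2.shape[1]}"
            )
        p = self.params
        h1 = _relu(x2 @ p["We1"] + p["be1"])
        h2 = _relu(h1 @ p["We2"] + p["be2"])
        out = h2 @ p["We3"] + p["be3"]
        L = self.config.latent_dim
        mu, log_var = out[:, :L], out[:, L:]
        if squeeze:
            mu, log_var = mu[0], log_var[0]
        return LatentStats(mu=mu, log_var=log_var)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Map latent vectors back to signal space; accepts one vector or a batch."""
        z = np.asarray(z, dtype=float)
        squeeze = z.ndim == 1
        z2 = np.atleast_2d(z)
        if z2.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"expected latent dimension {self.config.latent_dim}, got {z2.shape[1]}"
            )
        p = self.params
        d1 = _relu(z2 @ p["Wd1"] + p["bd1"])
        d2 = _relu(d1 @ p["Wd2"] + p["bd2"])
        x_hat = d2 @ p["Wd3"] + p["bd3"]
        return x_hat[0] if squeeze else x_hat

    def reconstruct(self, x: np.ndarray, epsilon: np.ndarray | float = 0.0) -> np.ndarray:
        """Convenience: decode(reparameterize(encode(x), epsilon))."""
        stats = self.encode(x)
        return self.decode(reparameterize(stats, epsilon=epsilon))

    # --------------------------------------------------- forward+backward pass

    def _step_gradients(
        self, x: np.ndarray, eps: np.ndarray, beta: float
    ) -> tuple[dict[str, np.ndarray], float, float, float]:
        """One forward/backward pass on a batch; returns grads and loss parts."""
        p = self.params
        B, D = x.shape
        L = self.config.latent_dim

        a1 = x @ p["We1"] + p["be1"]; h1 = _relu(a1)
        a2 = h1 @ p["We2"] + p["be2"]; h2 = _relu(a2)
        out = h2 @ p["We3"] + p["be3"]
        mu, log_var = out[:, :L], out[:, L:]
        sigma = np.exp(0.5 * log_var)
        z = mu + eps * sigma
        a4 = z @ p["Wd1"] + p["bd1"]; d1 = _relu(a4)
        a5 = d1 @ p["Wd2"] + p["bd2"]; d2 = _relu(a5)
        x_hat = d2 @ p["Wd3"] + p["bd3"]

        recon = float(np.mean((x - x_hat) ** 2))
        kl = float(np.mean(-0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var), axis=1)))
        total = recon + beta * kl

        g: dict[str, np.ndarray] = {}
        g_xhat = 2.0 * (x_hat - x) / (B * D)
        g["Wd3"] = d2.T @ g_xhat; g["bd3"] = g_xhat.sum(axis=0)
        g_d2 = (g_xhat @ p["Wd3"].T) * (a5 > 0)
        g["Wd2"] = d1.T @ g_d2; g["bd2"] = g_d2.sum(axis=0)
        g_d1 = (g_d2 @ p["Wd2"].T) * (a4 > 0)
        g["Wd1"] = z.T @ g_d1; g["bd1"] = g_d1.sum(axis=0)
        g_z = g_d1 @ p["Wd1"].T
        # dz/dmu = 1, dz/dlog_var = 0.5 * eps * sigma; KL adds mu/B and 0.5(e^lv-1)/B
        g_mu = g_z + beta * mu / B
        g_lv = g_z * eps * 0.5 * sigma + beta * 0.5 * (np.exp(log_var) - 1.0) / B
        g_out = np.concatenate([g_mu, g_lv], axis=1)
        g["We3"] = h2.T @ g_out; g["be3"] = g_out.sum(axis=0)
        g_h2 = (g_out @ p["We3"].T) * (a2 > 0)
        g["We2"] = h1.T @ g_h2; g["be2"] = g_h2.sum(axis=0)
        g_h1 = (g_h2 @ p["We2"].T) * (a1 > 0)
        g["We1"] = x.T @ g_h1; g["be1"] = g_h1.sum(axis=0)
        return g, total, recon, kl


def reparameterize(
    stats: LatentStats,
    epsilon: np.ndarray | float | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Sample z = mu + epsilon * sigma with sigma = exp(log_var / 2).

    Provide either an explicit ``epsilon`` (array broadcastable to ``mu``, or
    a scalar) or a ``seed`` from which a standard-normal draw is generated.
    """
    if epsilon is None:
        if seed is None:
            raise ValueError("provide either epsilon or seed")
        rng = np.random.default_rng(seed)
        epsilon = rng.standard_normal(stats.mu.shape)
    epsilon = np.asarray(epsilon, dtype=float)
    if epsilon.ndim > 0 and epsilon.shape[-1] != stats.mu.shape[-1]:
        raise ValueError("epsilon length must match latent dimension")
    return stats.mu + epsilon * stats.sigma


def kl_divergence(stats: LatentStats) -> float:
    """KL(N(mu, sigma^2) || N(0, I)), closed form, summed over latent dims.

    For a batch of stats the per-signal KLs are averaged.
    """
    term = -0.5 * (1.0 + stats.log_var - stats.mu**2 - np.exp(stats.log_var))
    if stats.mu.ndim == 1:
        return float(term.sum())
    return float(term.sum(axis=1).mean())


def total_loss(
    x: np.ndarray, x_hat: np.ndarray, stats: LatentStats, beta: float = 1.0
) -> tuple[float, float, float]:
    """Return (total, reconstruction MSE, KL) with total = recon + beta*KL."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have equal shapes")
    recon = float(np.mean((x - x_hat) ** 2))
    kl = kl_divergence(stats)
    return recon + beta * kl, recon, kl


def train(
    model: VAE,
    data: np.ndarray,
    config: VAEConfig | None = None,
    val_data: np.ndarray | None = None,
) -> tuple[VAE, TrainingHistory]:
    """Train the VAE in place on an (n_signals, input_dim) array.

    Uses Adam by default (plain SGD via ``config.optimizer``).  Loss history
    is recorded per epoch.  Raises on an empty dataset and aborts with a
    diagnostic if the loss turns non-finite.
    """
    if config is None:
        config = model.config
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("training data must be a nonempty (n_signals, input_dim) array")
    if data.shape[1] != config.input_dim:
        raise ValueError("training data width must equal input_dim")

    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    eps_rng = np.random.default_rng(ss.spawn(1)[0])

    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in model.params.items()}
    t = 0
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    history = TrainingHistory()
    n = data.shape[0]
    best_val = np.inf
    stall = 0

    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        ep_tot = ep_rec = ep_kl = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            eps = eps_rng.standard_normal((batch.shape[0], config.latent_dim))
            grads, tot, rec, kl = model._step_gradients(batch, eps, config.beta)
            if not np.isfinite(tot):
                raise RuntimeError(
                    f"non-finite loss at epoch {_epoch}: total={tot}, recon={rec}, kl={kl}"
                )
            t += 1
            for k in model.params:
                if config.optimizer == "adam":
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    m_hat = m[k] / (1 - b1**t)
                    v_hat = v[k] / (1 - b2**t)
                    model.params[k] -= lr * m_hat / (np.sqrt(v_hat) + adam_eps)
                else:
                    model.params[k] -= lr * grads[k]
            ep_tot += tot; ep_rec += rec; ep_kl += kl
            n_batches += 1
        history.total.append(ep_tot / n_batches)
        history.recon.append(ep_rec / n_batches)
        history.kl.append(ep_kl / n_batches)

        if val_data is not None and len(val_data):
            stats = model.encode(val_data)
            x_hat = model.decode(reparameterize(stats, epsilon=0.0))
            vt, _, _ = total_loss(val_data, x_hat, stats, config.beta)
            history.val_total.append(vt)
            if config.early_stopping:
                if vt < best_val - 1e-12:
                    best_val = vt
                    stall = 0
                else:
                    stall += 1
                    if stall >= config.patience:
                        break
    return model, history


def save_model(model: VAE, path: str) -> None:
    """Serialize parameters + config to an .npz checkpoint."""
    cfg = asdict(model.config)
    cfg["hidden_dims"] = list(cfg["hidden_dims"])
    np.savez(path, __config__=np.array(json.dumps(cfg)), **model.params)


def load_model(path: str) -> VAE:
    """Restore a VAE from an .npz checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        cfg = json.loads(str(data["__config__"]))
        cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
        model = VAE(VAEConfig(**cfg))
        for k in model.PARAM_NAMES:
            model.params[k] = data[k]
    return model
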