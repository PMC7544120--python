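"""Variational autoencoder over binary contact vectors.

The generative model is p(Q) = integral p(Q|z) p(z) dz with a standard
multivariate Gaussian prior p(z), a Bernoulli decoder p(Q|z) and a diagonal
Gaussian encoder q(z|Q), each a single-hidden-layer (200 unit, ReLU) network.
Training maximizes the evidence lower bound

    log P_VAE(Q) >= E_q[log p(Q|z)] - KL[q(z|Q) || p(z)]

by stochastic gradient ascent (Adam, reparameterization trick).  The trained
lower bound doubles as the structure's log-probability estimate, the bridge
to the free-energy analysis: F(Q) = -log P_VAE(Q) in units of k_B T.

Two model roles are used and never mixed: a 2-latent model whose posterior
means define the visualizable embedding behind the folding coordinate, and
25-latent models used for all probability / energy estimates.

Implemented directly on NumPy (forward, analytic backward, Adam); the
networks are small enough that this is fast on a single CPU and keeps the
estimator fully deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VAEArchitecture",
    "TrainConfig",
    "VAEModel",
    "LogProbEstimate",
    "TrainingError",
    "train_vae",
    "encode",
    "decode",
    "estimate_log_prob",
    "estimate_log_prob_batch",
    "iwae_log_prob",
    "sample_contacts",
    "save_model",
    "load_model",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class VAEArchitecture:
    input_dim: int
    hidden_dim: int = 200
    latent_dim: int = 25

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_dim, self.latent_dim) < 1:
            raise ValueError("all dimensions must be positive")


@dataclass
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class VAEModel:
    arch: VAEArchitecture
    params: dict[str, np.ndarray]
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def copy(self) -> "VAEModel":
        return VAEModel(self.arch, {k: v.copy() for k, v in self.params.items()},
                        self.loss_history.copy())


@dataclass
class LogProbEstimate:
    """Monte-Carlo ELBO in nats; a lower bound on log P_VAE(Q), always <= 0."""

    value: float
    n_samples: int


# --------------------------------------------------------------------------
# numerics
# --------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_params(arch: VAEArchitecture, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He init for ReLU layers, fan-in scaling for linear heads; float32."""
    d_in, d_h, d_z = arch.input_dim, arch.hidden_dim, arch.latent_dim

    def w(fan_in, fan_out, gain):
        return (gain / np.sqrt(fan_in) * rng.standard_normal((fan_in, fan_out))).astype(
            np.float32
        )

    return {
        "W1": w(d_in, d_h, np.sqrt(2.0)), "b1": np.zeros(d_h, np.float32),
        "Wm": w(d_h, d_z, 1.0), "bm": np.zeros(d_z, np.float32),
        "Wv": w(d_h, d_z, 1.0), "bv": np.zeros(d_z, np.float32),
        "W2": w(d_z, d_h, np.sqrt(2.0)), "b2": np.zeros(d_h, np.float32),
        "W3": w(d_h, d_in, 1.0), "b3": np.zeros(d_in, np.float32),
    }


def _encode_batch(p: dict, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pre1 = x @ p["W1"] + p["b1"]
    h1 = np.maximum(pre1, 0.0)
    return h1 @ p["Wm"] + p["bm"], h1 @ p["Wv"] + p["bv"], h1


def _decode_batch(p: dict, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pre2 = z @ p["W2"] + p["b2"]
    h2 = np.maximum(pre2, 0.0)
    return h2 @ p["W3"] + p["b3"], h2


def _elbo_terms(logits: np.ndarray, x: np.ndarray, mu: np.ndarray,
                lv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log p(x|z), KL) per row.  log p = x*l - softplus(l) summed over features."""
    rec = np.sum(x * logits - _softplus(logits), axis=-1)
    kl = 0.5 * np.sum(np.exp(lv) + mu * mu - 1.0 - lv, axis=-1)
    return rec, kl


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train_vae(X: np.ndarray, arch: VAEArchitecture, cfg: TrainConfig) -> VAEModel:
    """Fit the VAE by maximizing the ELBO with Adam; deterministic under seed.

    ``X`` is (n_cells, input_dim) binary.  Records the per-epoch mean negative
    ELBO in ``loss_history``.  Raises :class:`TrainingError` on a non-finite
    loss, reporting the epoch.
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty (n, input_dim) array")
    if X.shape[1] != arch.input_dim:
        raise ValueError(f"X has {X.shape[1]} features, arch expects {arch.input_dim}")

    rng = np.random.default_rng(cfg.seed)
    p = _init_params(arch, rng)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    t = 0
    n = X.shape[0]
    losses = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            xb = X[order[start : start + cfg.batch_size]]
            B = xb.shape[0]

            # forward
            pre1 = xb @ p["W1"] + p["b1"]
            h1 = np.maximum(pre1, 0.0)
            mu = h1 @ p["Wm"] + p["bm"]
            lv = h1 @ p["Wv"] + p["bv"]
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            std = np.exp(0.5 * lv)
            z = mu + std * eps
            pre2 = z @ p["W2"] + p["b2"]
            h2 = np.maximum(pre2, 0.0)
            logits = h2 @ p["W3"] + p["b3"]

            rec, kl = _elbo_terms(logits, xb, mu, lv)
            loss = float(np.mean(-rec + kl))
            epoch_loss += loss * B
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")

            # backward (gradients of mean negative ELBO)
            dlogits = (_sigmoid(logits) - xb) / B
            gW3 = h2.T @ dlogits
            gb3 = dlogits.sum(0)
            dh2 = dlogits @ p["W3"].T
            dpre2 = dh2 * (pre2 > 0)
            gW2 = z.T @ dpre2
            gb2 = dpre2.sum(0)
            dz = dpre2 @ p["W2"].T
            dmu = dz + mu / B
            dlv = dz * eps * (0.5 * std) + 0.5 * (np.exp(lv) - 1.0) / B
            gWm = h1.T @ dmu
            gbm = dmu.sum(0)
            gWv = h1.T @ dlv
            gbv = dlv.sum(0)
            dh1 = dmu @ p["Wm"].T + dlv @ p["Wv"].T
            dpre1 = dh1 * (pre1 > 0)
            gW1 = xb.T @ dpre1
            gb1 = dpre1.sum(0)

            grads = {"W1": gW1, "b1": gb1, "Wm": gWm, "bm": gbm, "Wv": gWv,
                     "bv": gbv, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                p[k] -= (lr_t * m[k] / (np.sqrt(v[k]) + eps_adam)).astype(np.float32)
        losses[epoch] = epoch_loss / n

    return VAEModel(arch=arch, params=p, loss_history=losses)


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _as_batch(x: np.ndarray, input_dim: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != input_dim:
        raise ValueError(f"input has {x.shape[1]} features, model expects {input_dim}")
    return x, single


def encode(model: VAEModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and log-variance; the mean is the latent embedding."""
    xb, single = _as_batch(x, model.arch.input_dim)
    mu, lv, _ = _encode_batch(model.params, xb)
    if single:
        return mu[0], lv[0]
    return mu, lv


def decode(model: VAEModel, z: np.ndarray) -> np.ndarray:
    """Bernoulli probabilities p(Q_i = 1 | z)."""
    z = np.asarray(z, dtype=np.float32)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != model.arch.latent_dim:
        raise ValueError("latent dimension mismatch")
    logits, _ = _decode_batch(model.params, z)
    probs = _sigmoid(logits)
    return probs[0] if single else probs


def estimate_log_prob_batch(
    model: VAEModel,
    X: np.ndarray,
    n_samples: int = 20,
    seed: int | None = None,
    eps: np.ndarray | None = None,
) -> np.ndarray:
    """ELBO estimates (nats) for each row of X.

    Monte-Carlo mean of log p(Q|z) over ``n_samples`` posterior draws minus
    the closed-form Gaussian KL.  ``eps`` — standard-normal draws of shape
    (n_samples, n, latent_dim) — may be supplied to share randomness between
    models (variance reduction when differencing log-probabilities).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    Xb, _ = _as_batch(X, model.arch.input_dim)
    mu, lv, _ = _encode_batch(model.params, Xb)
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((n_samples, Xb.shape[0], model.arch.latent_dim))
    eps = np.asarray(eps, dtype=np.float32)
    if eps.shape != (n_samples, Xb.shape[0], model.arch.latent_dim):
        raise ValueError("eps has wrong shape")
    std = np.exp(0.5 * lv)
    rec_sum = np.zeros(Xb.shape[0])
    for s in range(n_samples):
        z = mu + std * eps[s]
        logits, _ = _decode_batch(model.params, z)
        rec, _ = _elbo_terms(logits, Xb, mu, lv)
        rec_sum += rec
    kl = 0.5 * np.sum(np.exp(lv) + mu * mu - 1.0 - lv, axis=-1)
    return rec_sum / n_samples - kl


def estimate_log_prob(
    model: VAEModel,
    x: np.ndarray,
    n_samples: int = 20,
    seed: int | None = None,
    eps: np.ndarray | None = None,
) -> LogProbEstimate:
    """ELBO estimate of log P_VAE(Q) for a single contact vector."""
    vals = estimate_log_prob_batch(model, np.atleast_2d(x), n_samples, seed, eps)
    return LogProbEstimate(value=float(vals[0]), n_samples=n_samples)


def iwae_log_prob(model: VAEModel, x: np.ndarray, k: int = 50,
                  seed: int | None = None) -> float:
    """Importance-weighted bound with k samples; tighter than the ELBO."""
    xb, _ = _as_batch(np.atleast_2d(x), model.arch.input_dim)
    mu, lv, _ = _encode_batch(model.params, xb)
    rng = np.random.default_rng(seed)
    std = np.exp(0.5 * lv)
    logw = np.empty((k, xb.shape[0]))
    for s in range(k):
        e = rng.standard_normal(mu.shape).astype(np.float32)
        z = mu + std * e
        logits, _ = _decode_batch(model.params, z)
        rec = np.sum(xb * logits - _softplus(logits), axis=-1)
        log_prior = -0.5 * np.sum(z * z + np.log(2 * np.pi), axis=-1)
        log_q = -0.5 * np.sum(e * e + np.log(2 * np.pi) + lv, axis=-1)
        logw[s] = rec + log_prior - log_q
    from scipy.special import logsumexp

    return float((logsumexp(logw, axis=0) - np.log(k))[0])


def sample_contacts(model: VAEModel, n: int, seed: int | None = None) -> list[np.ndarray]:
    """Generate contact matrices: z ~ p(z), decode, Bernoulli draw, symmetrize."""
    from .preprocess import matrix_from_vector

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.arch.latent_dim)).astype(np.float32)
    probs = decode(model, z)
    draws = (rng.random(probs.shape) < probs).astype(float)
    # infer matrix size from the feature length
    L = model.arch.input_dim
    n_bins = int(round((1 + np.sqrt(1 + 8 * L)) / 2))
    return [matrix_from_vector(row, n_bins) for row in draws]


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_model(model: VAEModel, path) -> None:
    np.savez(
        path,
        input_dim=model.arch.input_dim,
        hidden_dim=model.arch.hidden_dim,
        latent_dim=model.arch.latent_dim,
        loss_history=model.loss_history,
        **{f"param_{k}": v for k, v in model.params.items()},
    )


def load_model(path) -> VAEModel:
    data = np.load(path)
    arch = VAEArchitecture(
        input_dim=int(data["input_dim"]),
        hidden_dim=int(data["hidden_dim"]),
        latent_dim=int(data["latent_dim"]),
    )
    params = {k[6:]: data[k] for k in data.files if k.startswith("param_")}
    return VAEModel(arch=arch, params=params, loss_history=data["loss_history"])
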