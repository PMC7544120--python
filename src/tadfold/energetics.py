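"""Free-energy decomposition of contact formation, F(Q) = U(Q) - T S(Q).

-log P_VAE(Q) estimates the contact free energy up to a constant.  Its
entropic part is generic (depends only on polymer length and flexibility),
so subtracting the log-probability of the *same* structure under a VAE
trained on a reference homopolymer of equal length cancels it:

    -log [P_VAE(Q) / P_VAE_ref(Q)]  ~  U(Q) - U_ref(Q) = Delta U(Q),

the specific interaction energy.  This module computes that difference,
profiles of energies along the folding coordinate, the mixing-entropy
correction that converts the conditional mean free energy into the free
energy of the coordinate itself, and the reference-model entropy profile.
All energies are in k_B T = nats (T = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vae import VAEModel, estimate_log_prob_batch

__all__ = [
    "EnergyProfile",
    "interaction_energy",
    "interaction_energy_batch",
    "profile_along_coordinate",
    "mixing_entropy",
    "coordinate_free_energy",
    "reference_entropy_profile",
]


@dataclass
class EnergyProfile:
    """Binned statistic along the folding coordinate (bin centers at multiples of the width)."""

    centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray


def _shared_eps(model: VAEModel, n_rows: int, n_samples: int,
                seed: int | None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_samples, n_rows, model.arch.latent_dim)).astype(np.float32)


def interaction_energy_batch(
    model: VAEModel,
    model_ref: VAEModel,
    X: np.ndarray,
    n_samples: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """-log[P_VAE(Q)/P_VAE_ref(Q)] per row of X, in k_B T.

    The same latent-noise draws are used for both models (their latent
    dimensions match by construction), which cancels most Monte-Carlo noise
    of the ratio; with identical models the result is exactly zero.
    """
    if model.arch.input_dim != model_ref.arch.input_dim:
        raise ValueError("models expect different input dimensions")
    if model.arch.latent_dim != model_ref.arch.latent_dim:
        raise ValueError("models have different latent dimensions")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eps = _shared_eps(model, X.shape[0], n_samples, seed)
    logp = estimate_log_prob_batch(model, X, n_samples, eps=eps)
    logp_ref = estimate_log_prob_batch(model_ref, X, n_samples, eps=eps)
    return logp_ref - logp


def interaction_energy(
    model: VAEModel,
    model_ref: VAEModel,
    q_vector: np.ndarray,
    n_samples: int = 20,
    seed: int | None = None,
) -> float:
    """Specific interaction energy of one structure (k_B T); see module docstring."""
    return float(interaction_energy_batch(model, model_ref, q_vector, n_samples, seed)[0])


def profile_along_coordinate(values: np.ndarray, coordinates: np.ndarray,
                             bin_width: float = 0.4) -> EnergyProfile:
    """Per-bin mean/sd/count of ``values`` binned by folding coordinate.

    Bin centers sit at integer multiples of ``bin_width`` (bin = nearest
    multiple); empty bins are omitted.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    if values.shape != coords.shape:
        raise ValueError("values and coordinates must have equal length")
    idx = np.round(coords / bin_width).astype(int)
    uniq = np.unique(idx)
    centers, mean, sd, count = [], [], [], []
    for u in uniq:
        sel = idx == u
        centers.append(u * bin_width)
        mean.append(float(np.mean(values[sel])))
        sd.append(float(np.std(values[sel], ddof=0)))
        count.append(int(np.sum(sel)))
    return EnergyProfile(
        centers=np.asarray(centers), mean=np.asarray(mean),
        sd=np.asarray(sd), count=np.asarray(count),
    )


def mixing_entropy(mean_contact_probs: np.ndarray) -> float:
    """S(q) = sum_ij Q_ij log Q_ij + (1 - Q_ij) log(1 - Q_ij), in nats.

    ``mean_contact_probs`` are the per-pair contact probabilities of the
    structures in one coordinate bin; 0 log 0 = 0, and the sum is always <= 0.
    """
    p = np.asarray(mean_contact_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("contact probabilities must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0) + np.where(
            p < 1, (1.0 - p) * np.log(1.0 - p), 0.0
        )
    return float(np.sum(terms))


def coordinate_free_energy(
    mean_f: np.ndarray, mixing_entropies: np.ndarray, T: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """F(q) = <F(Q)>_q - T S(q) and the Boltzmann distribution it implies.

    Returns (F, P) over aligned coordinate bins with P = exp(-F)/sum exp(-F).
    """
    mean_f = np.asarray(mean_f, dtype=float)
    s = np.asarray(mixing_entropies, dtype=float)
    if mean_f.shape != s.shape:
        raise ValueError("profiles are misaligned")
    F = mean_f - T * s
    w = np.exp(-(F - F.min()))
    return F, w / w.sum()


def reference_entropy_profile(
    logp_ref: np.ndarray, coordinates: np.ndarray, bin_width: float = 0.4
) -> EnergyProfile:
    """Entropy change along the coordinate, Delta S(q) ~ Delta log P_VAE_ref.

    The reference homopolymer's interaction energy is nearly constant across
    folding states, so the variation of its log-probability is entropic.
    Values are shifted so the lowest occupied bin is zero.
    """
    prof = profile_along_coordinate(logp_ref, coordinates, bin_width)
    shifted = prof.mean - prof.mean[0]
    return EnergyProfile(centers=prof.centers, mean=shifted, sd=prof.sd, count=prof.count)
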