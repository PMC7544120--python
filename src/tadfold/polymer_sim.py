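"""Coarse-grained polymer models of a 2.5 Mb chromatin region.

A 28-bead bead-spring chain (one bead per 90 kb) is simulated with underdamped
Langevin dynamics in reduced units (sigma, epsilon, tau).  Two variants are
used throughout the package:

* the *reference* (homopolymer) model: harmonic bonds, a capped soft-core
  repulsion that permits chain crossing, and a weak uniform collapse
  attraction tuned so that adjacent beads are in contact (r <= 3.0 sigma)
  about 80% of the time, matching imaging data at 90 kb resolution;
* the *chromatin-like* model: the reference potential plus an additional
  attraction restricted to bead pairs lying within the same half of the
  chain, which promotes the formation of two domains (TADs).

The difference of the two potentials evaluated on a chromatin-like
configuration, ``specific_energy_delta``, is the ground-truth interaction
energy that the VAE-based estimate is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "PolymerModelParams",
    "EnergyDecomposition",
    "IntegrationError",
    "bonded_energy",
    "softcore_energy",
    "collapse_energy",
    "specific_energy_delta",
    "contact_energy",
    "total_energy",
    "forces",
    "run_langevin",
    "contacts_from_conformation",
]


class IntegrationError(RuntimeError):
    """Raised when the Langevin integrator produces non-finite coordinates."""


@dataclass
class PolymerModelParams:
    """All constants of the coarse-grained polymer energy function.

    Energies in epsilon, lengths in sigma, times in tau.  ``collapse_alpha``
    is the uniform non-bonded attraction of the reference model and
    ``specific_alpha`` the extra same-half attraction of the chromatin-like
    model, both expressed as the well depth *per unordered pair*.  The
    conventional interaction strengths alpha = -0.04 and -0.1 are defined
    through a symmetric double sum in which every pair appears twice, so the
    per-pair defaults are 2 alpha = -0.08 and -0.2.  ``damping`` is the
    Langevin damping *time* (the friction rate is 1/damping).
    """

    n_beads: int = 28
    bond_k: float = 1.0
    bond_r0: float = 2.0
    softcore_cap: float = 4.0
    collapse_alpha: float = -0.08
    collapse_eta: float = 10.0
    collapse_rc: float = 3.0
    specific_alpha: float = -0.2
    domain_split: int | None = None  # defaults to the chain midpoint
    timestep: float = 0.01
    damping: float = 0.5
    temperature: float = 1.0
    contact_cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.collapse_rc <= 0:
            raise ValueError("collapse_rc must be positive")
        if self.domain_split is None:
            self.domain_split = self.n_beads // 2
        if not (0 <= self.domain_split <= self.n_beads):
            raise ValueError("domain_split must lie in [0, n_beads]")

    # pair bookkeeping -----------------------------------------------------
    def _nonbonded_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (i, j) of all pairs with |i - j| >= 2, i < j."""
        i, j = np.triu_indices(self.n_beads, k=2)
        return i, j

    def _samehalf_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Non-bonded pairs with both beads in the same half of the chain."""
        i, j = self._nonbonded_pairs()
        s = self.domain_split
        keep = ((i < s) & (j < s)) | ((i >= s) & (j >= s))
        return i[keep], j[keep]


@dataclass
class EnergyDecomposition:
    """Per-term potential energy of one conformation, in epsilon."""

    bonded: float
    softcore: float
    collapse: float
    specific: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.bonded + self.softcore + self.collapse + self.specific


def _check_conformation(conf: np.ndarray, params: PolymerModelParams) -> np.ndarray:
    conf = np.asarray(conf, dtype=float)
    if conf.ndim != 2 or conf.shape[1] != 3:
        raise ValueError(f"conformation must be (n_beads, 3), got {conf.shape}")
    if conf.shape[0] != params.n_beads:
        raise ValueError(
            f"conformation has {conf.shape[0]} beads, params expect {params.n_beads}"
        )
    if conf.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    if not np.all(np.isfinite(conf)):
        raise ValueError("conformation contains non-finite coordinates")
    return conf


# --------------------------------------------------------------------------
# energy terms
# --------------------------------------------------------------------------

def bonded_energy(conf: np.ndarray, params: PolymerModelParams) -> float:
    """Harmonic bond energy sum_i k (r_{i,i+1} - r0)^2.

    Uses the U = k (r - r0)^2 convention (no 1/2 factor).
    """
    conf = _check_conformation(conf, params)
    r = np.linalg.norm(np.diff(conf, axis=0), axis=1)
    return float(params.bond_k * np.sum((r - params.bond_r0) ** 2))


# WCA (purely repulsive Lennard-Jones) parameters of the soft core: bead
# diameter of one length unit (half the bond rest length, so neighboring
# blobs interpenetrate freely within the contact range) and depth 1 epsilon.
_LJ_SIGMA = 1.0
_LJ_EPS = 1.0
_LJ_CUT = 2.0 ** (1.0 / 6.0) * _LJ_SIGMA


def _wca(r: np.ndarray) -> np.ndarray:
    """Truncated-shifted repulsive LJ; zero at and beyond the cutoff."""
    r = np.maximum(r, 1e-12)
    s6 = (_LJ_SIGMA / r) ** 6
    u = 4.0 * _LJ_EPS * (s6 * s6 - s6) + _LJ_EPS
    return np.where(r < _LJ_CUT, u, 0.0)


def _softcore_from_wca(u: np.ndarray, cap: float) -> np.ndarray:
    # blend the diverging WCA wall into a finite plateau at `cap`
    with np.errstate(over="ignore"):
        blended = 0.5 * cap * (1.0 + np.tanh(2.0 * np.minimum(u, 1e6) / cap - 1.0))
    return np.where(u > 0.0, blended, 0.0)


def softcore_energy(conf: np.ndarray, params: PolymerModelParams) -> float:
    """Capped soft-core repulsion over all non-bonded pairs.

    Finite for fully overlapping beads (equals ``softcore_cap`` per pair at
    r = 0), which allows chain crossing during the dynamics.
    """
    conf = _check_conformation(conf, params)
    i, j = params._nonbonded_pairs()
    r = np.linalg.norm(conf[i] - conf[j], axis=1)
    return float(np.sum(_softcore_from_wca(_wca(r), params.softcore_cap)))


def _tanh_well(r: np.ndarray, alpha: float, eta: float, rc: float) -> np.ndarray:
    return 0.5 * alpha * (1.0 + np.tanh(eta * (rc - r)))


def collapse_energy(
    conf: np.ndarray, params: PolymerModelParams, alpha: float | None = None
) -> float:
    """Uniform short-range attraction sum_{|i-j|>=2} (alpha/2)[1 + tanh(eta (r_c - r))]."""
    conf = _check_conformation(conf, params)
    if alpha is None:
        alpha = params.collapse_alpha
    i, j = params._nonbonded_pairs()
    r = np.linalg.norm(conf[i] - conf[j], axis=1)
    return float(np.sum(_tanh_well(r, alpha, params.collapse_eta, params.collapse_rc)))


def specific_energy_delta(conf: np.ndarray, params: PolymerModelParams) -> float:
    """Extra same-half attraction of the chromatin-like model, Delta U(Q).

    The tanh well with strength ``specific_alpha`` summed over non-bonded
    pairs whose beads both lie in [0, domain_split) or both in
    [domain_split, n_beads).  This is the ground-truth interaction-energy
    difference between the chromatin-like and reference models.
    """
    conf = _check_conformation(conf, params)
    i, j = params._samehalf_pairs()
    r = np.linalg.norm(conf[i] - conf[j], axis=1)
    return float(
        np.sum(_tanh_well(r, params.specific_alpha, params.collapse_eta, params.collapse_rc))
    )


def contact_energy(
    conf: np.ndarray, params: PolymerModelParams, chromatin_like: bool = False
) -> float:
    """Non-bonded contact energy U(Q): collapse plus (if chromatin-like) specific term.

    This is the part of the potential that is a functional of the contact
    matrix — bonded and soft-core terms are generic chain properties — and is
    the quantity the raw VAE free energy is compared against.
    """
    u = collapse_energy(conf, params)
    if chromatin_like:
        u += specific_energy_delta(conf, params)
    return u


def total_energy(
    conf: np.ndarray, params: PolymerModelParams, chromatin_like: bool = False
) -> EnergyDecomposition:
    """Full potential energy decomposition of one conformation."""
    spec = specific_energy_delta(conf, params) if chromatin_like else 0.0
    return EnergyDecomposition(
        bonded=bonded_energy(conf, params),
        softcore=softcore_energy(conf, params),
        collapse=collapse_energy(conf, params),
        specific=spec,
    )


# --------------------------------------------------------------------------
# forces
# --------------------------------------------------------------------------

def forces(
    conf: np.ndarray,
    params: PolymerModelParams,
    chromatin_like: bool = False,
    *,
    _pairs: tuple | None = None,
) -> np.ndarray:
    """Analytic forces of the total potential; shape (n_beads, 3)."""
    conf = np.asarray(conf, dtype=float)
    n = params.n_beads
    f = np.zeros_like(conf)

    # bonds
    dvec = conf[1:] - conf[:-1]
    r = np.linalg.norm(dvec, axis=1)
    r_safe = np.maximum(r, 1e-12)
    # dU/dr = 2 k (r - r0); force on bead i+1 is -dU/dr * rhat
    coef = -2.0 * params.bond_k * (r - params.bond_r0) / r_safe
    fb = coef[:, None] * dvec
    f[1:] += fb
    f[:-1] -= fb

    if _pairs is None:
        i, j = params._nonbonded_pairs()
        s = params.domain_split
        samehalf = ((i < s) & (j < s)) | ((i >= s) & (j >= s))
    else:
        i, j, samehalf = _pairs
    dvec = conf[i] - conf[j]
    r = np.linalg.norm(dvec, axis=1)
    r_safe = np.maximum(r, 1e-12)

    # soft core: dU_sc/dr = sech^2(2 u/cap - 1) * du/dr  (u = WCA energy)
    cap = params.softcore_cap
    inside = r < _LJ_CUT
    dudr = np.zeros_like(r)
    if np.any(inside):
        ri = r_safe[inside]
        s6 = (_LJ_SIGMA / ri) ** 6
        du = 4.0 * _LJ_EPS * (-12.0 * s6 * s6 + 6.0 * s6) / ri
        u = 4.0 * _LJ_EPS * (s6 * s6 - s6) + _LJ_EPS
        arg = np.minimum(2.0 * u / cap - 1.0, 30.0)
        sech2 = 1.0 / np.cosh(arg) ** 2
        dudr[inside] = sech2 * du

    # collapse attraction: dU/dr = -(alpha eta / 2) sech^2(eta (rc - r))
    eta, rc = params.collapse_eta, params.collapse_rc
    arg = np.clip(eta * (rc - r), -30.0, 30.0)
    sech2 = 1.0 / np.cosh(arg) ** 2
    dudr += -0.5 * params.collapse_alpha * eta * sech2
    if chromatin_like:
        dudr += np.where(samehalf, -0.5 * params.specific_alpha * eta * sech2, 0.0)

    coef = -dudr / r_safe
    fp = coef[:, None] * dvec
    np.add.at(f, i, fp)
    np.add.at(f, j, -fp)
    return f


# --------------------------------------------------------------------------
# Langevin dynamics
# --------------------------------------------------------------------------

def initial_conformation(params: PolymerModelParams, rng: np.random.Generator) -> np.ndarray:
    """Straight chain at the bond rest length plus 0.1 sigma Gaussian jitter."""
    conf = np.zeros((params.n_beads, 3))
    conf[:, 0] = np.arange(params.n_beads) * params.bond_r0
    conf += 0.1 * rng.standard_normal(conf.shape)
    return conf


def run_langevin(
    params: PolymerModelParams,
    n_steps: int,
    save_every: int,
    seed: int,
    *,
    chromatin_like: bool = False,
    n_equilibration: int = 10_000,
    initial: np.ndarray | None = None,
    return_kinetic: bool = False,
):
    """Underdamped Langevin (BAOAB splitting) trajectory of the polymer.

    Unit bead mass; the friction rate is 1/``params.damping``.  Returns an
    array of saved conformations of shape (n_steps // save_every, n_beads, 3)
    — frame f is the configuration after (f + 1) * save_every production
    steps.  With ``return_kinetic`` also returns the kinetic energy per bead
    at each saved frame.  Identical seeds give bitwise-identical output.
    """
    if not (n_steps >= save_every >= 1):
        raise ValueError("require n_steps >= save_every >= 1")
    rng = np.random.Generator(np.random.Philox(seed))
    dt = params.timestep
    gamma = 1.0 / params.damping
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * params.temperature)  # unit mass

    x = initial_conformation(params, rng) if initial is None else np.array(initial, dtype=float)
    v = math.sqrt(params.temperature) * rng.standard_normal(x.shape)

    i, j = params._nonbonded_pairs()
    s = params.domain_split
    samehalf = ((i < s) & (j < s)) | ((i >= s) & (j >= s))
    pairs = (i, j, samehalf)

    n_frames = n_steps // save_every
    frames = np.empty((n_frames, params.n_beads, 3))
    kinetic = np.empty(n_frames) if return_kinetic else None

    f = forces(x, params, chromatin_like, _pairs=pairs)
    frame = 0
    total = n_equilibration + n_steps
    for step in range(total):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f = forces(x, params, chromatin_like, _pairs=pairs)
        v += 0.5 * dt * f
        if step >= n_equilibration:
            prod_step = step - n_equilibration + 1
            if prod_step % save_every == 0:
                if not np.all(np.isfinite(x)):
                    raise IntegrationError(f"non-finite coordinates at step {step}")
                frames[frame] = x
                if return_kinetic:
                    kinetic[frame] = 0.5 * np.sum(v * v) / params.n_beads
                frame += 1
    if not np.all(np.isfinite(frames[:frame])):
        raise IntegrationError("non-finite coordinates in saved frames")
    if return_kinetic:
        return frames, kinetic
    return frames


def contacts_from_conformation(conf: np.ndarray, cutoff: float) -> np.ndarray:
    """Binary symmetric contact matrix: Q_ij = 1 iff r_ij <= cutoff.

    The diagonal is 1 by convention (distance zero); it is excluded from all
    downstream feature vectors.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    conf = np.asarray(conf, dtype=float)
    d = np.linalg.norm(conf[:, None, :] - conf[None, :, :], axis=-1)
    return (d <= cutoff).astype(np.int8)


def write_xyz(frames: np.ndarray, path) -> None:
    """Write a trajectory as plain-text XYZ-like frames (index, x, y, z in sigma)."""
    frames = np.asarray(frames)
    with open(path, "w") as fh:
        for k, conf in enumerate(frames):
            fh.write(f"# frame {k}\n")
            for b, (x, y, z) in enumerate(conf):
                fh.write(f"{b}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_xyz(path, n_beads: int) -> np.ndarray:
    """Read a trajectory written by :func:`write_xyz`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
    arr = np.asarray(rows)
    if arr.size and arr.shape[0] % n_beads:
        raise ValueError("trajectory length is not a multiple of n_beads")
    return arr.reshape(-1, n_beads, 3)
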