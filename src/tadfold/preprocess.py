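"""Trace tables -> binarized, imputed, vectorized contact matrices.

Pipeline used on both imaging-like and simulated data: coarsen probes to the
working resolution (every third 30 kb probe -> 90 kb bins), build Euclidean
distance matrices, binarize at a distance cutoff (450 nm at 90 kb), impute
entries hit by missing probes from the sequence-separation-specific mean
contact probabilities of the dataset, and flatten the strict upper triangle
into the feature vector consumed by the VAE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_synth import CellTrace

__all__ = [
    "ContactMatrix",
    "SeparationProfile",
    "coarsen_trace",
    "distance_matrix",
    "binarize",
    "separation_profile",
    "impute_missing",
    "vectorize",
    "matrix_from_vector",
    "traces_to_feature_matrix",
]


@dataclass
class ContactMatrix:
    """Symmetric per-cell contact matrix.

    ``entries`` is float with values in {0, 1} and NaN for entries that are
    undefined because a probe was missing (until imputed).  ``imputed_mask``
    flags entries filled by imputation.
    """

    entries: np.ndarray
    imputed_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = self.entries.shape[0]
        if self.entries.shape != (n, n):
            raise ValueError("entries must be square")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros((n, n), dtype=bool)
        defined = np.isfinite(self.entries)
        if not np.array_equal(self.entries.T[defined.T], self.entries[defined]):
            raise ValueError("entries must be symmetric")
        vals = self.entries[defined]
        if vals.size and not np.all((vals == 0) | (vals == 1)):
            raise ValueError("defined entries must be binary")

    @property
    def n_bins(self) -> int:
        return self.entries.shape[0]

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.entries)))


@dataclass
class SeparationProfile:
    """Mean contact probability at each genomic separation s = 1 .. n-1."""

    probs: np.ndarray  # probs[s] valid for s >= 1; probs[0] unused (NaN)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        valid = np.isfinite(self.probs[1:])
        if np.any((self.probs[1:][valid] < 0) | (self.probs[1:][valid] > 1)):
            raise ValueError("profile values must be in [0, 1]")


def coarsen_trace(trace: CellTrace, factor: int) -> CellTrace:
    """Keep probes at indices 0, factor, 2*factor, ... (e.g. 30 kb -> 90 kb)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > trace.n_bins:
        raise ValueError(f"factor {factor} exceeds probe count {trace.n_bins}")
    if factor == 1:
        return trace
    idx = np.arange(0, trace.n_bins, factor)
    return CellTrace(
        cell_id=trace.cell_id,
        positions=trace.positions[idx],
        missing_mask=trace.missing_mask[idx],
        label=trace.label,
    )


def distance_matrix(trace: CellTrace) -> np.ndarray:
    """Pairwise Euclidean distances in nm; NaN where either probe is missing."""
    p = trace.positions
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    d[trace.missing_mask, :] = np.nan
    d[:, trace.missing_mask] = np.nan
    return d


def binarize(dist: np.ndarray, cutoff_nm: float) -> ContactMatrix:
    """Q_ij = 1 iff d_ij <= cutoff (ties are contacts); NaN stays NaN."""
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    dist = np.asarray(dist, dtype=float)
    q = np.where(np.isnan(dist), np.nan, (dist <= cutoff_nm).astype(float))
    return ContactMatrix(entries=q)


def separation_profile(matrices: list[ContactMatrix]) -> SeparationProfile:
    """Mean contact probability per separation over defined, non-imputed entries."""
    if not matrices:
        raise ValueError("need at least one matrix")
    n = matrices[0].n_bins
    sums = np.zeros(n)
    counts = np.zeros(n)
    ii, jj = np.triu_indices(n, k=1)
    s_idx = jj - ii
    for m in matrices:
        vals = m.entries[ii, jj]
        ok = np.isfinite(vals) & ~m.imputed_mask[ii, jj]
        np.add.at(sums, s_idx[ok], vals[ok])
        np.add.at(counts, s_idx[ok], 1)
    empty = [int(s) for s in range(1, n) if counts[s] == 0]
    if empty:
        raise ValueError(f"no defined entries at separations {empty}")
    probs = np.full(n, np.nan)
    probs[1:] = sums[1:] / counts[1:]
    return SeparationProfile(probs=probs)


def impute_missing(q: ContactMatrix, profile: SeparationProfile, seed: int) -> ContactMatrix:
    """Fill undefined entries with Bernoulli draws at the profile probability.

    Entry (i, j) with |i - j| = s is drawn Bernoulli(probs[s]) and mirrored;
    defined entries are never altered.  Deterministic under ``seed``.
    """
    n = q.n_bins
    if len(profile.probs) < n:
        raise ValueError("profile does not cover all separations")
    entries = q.entries.copy()
    imputed = q.imputed_mask.copy()
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n, k=1)
    undef = ~np.isfinite(entries[ii, jj])
    if np.any(undef):
        s = (jj - ii)[undef]
        p = profile.probs[s]
        if np.any(~np.isfinite(p)):
            raise ValueError("profile undefined at a required separation")
        draws = (rng.random(undef.sum()) < p).astype(float)
        entries[ii[undef], jj[undef]] = draws
        entries[jj[undef], ii[undef]] = draws
        imputed[ii[undef], jj[undef]] = True
        imputed[jj[undef], ii[undef]] = True
    np.fill_diagonal(entries, np.where(np.isfinite(np.diag(entries)), np.diag(entries), 1.0))
    return ContactMatrix(entries=entries, imputed_mask=imputed)


def vectorize(q: ContactMatrix | np.ndarray) -> np.ndarray:
    """Strict upper triangle (i < j), row-major; length n(n-1)/2."""
    entries = q.entries if isinstance(q, ContactMatrix) else np.asarray(q, dtype=float)
    ii, jj = np.triu_indices(entries.shape[0], k=1)
    vec = entries[ii, jj]
    if not np.all(np.isfinite(vec)):
        raise ValueError("matrix has undefined entries; impute first")
    return vec


def matrix_from_vector(vec: np.ndarray, n_bins: int) -> np.ndarray:
    """Inverse of :func:`vectorize`; diagonal set to 1."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != n_bins * (n_bins - 1) // 2:
        raise ValueError("vector length does not match n_bins")
    m = np.eye(n_bins)
    ii, jj = np.triu_indices(n_bins, k=1)
    m[ii, jj] = vec
    m[jj, ii] = vec
    return m


def traces_to_feature_matrix(
    traces: list[CellTrace],
    cutoff_nm: float = 450.0,
    coarsen: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Full preprocessing chain over a dataset.

    Coarsens, binarizes, computes the pooled separation profile, imputes, and
    vectorizes.  Returns (X of shape (n_cells, n_pairs), labels).
    """
    coarse = [coarsen_trace(t, coarsen) for t in traces]
    mats = [binarize(distance_matrix(t), cutoff_nm) for t in coarse]
    profile = separation_profile(mats)
    rng = np.random.default_rng(seed)
    filled = [
        impute_missing(m, profile, seed=int(rng.integers(0, 2**31)))
        for m in mats
    ]
    X = np.stack([vectorize(m) for m in filled])
    labels = [t.label for t in traces]
    return X, labels
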