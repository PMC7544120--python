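"""Ensemble-level structural diagnostics.

Mean distance maps, the boundary-score profile whose peaks mark TAD
boundaries (ratio of mean cross-window distance to the minimum mean
within-window distance, 180 kb windows), the per-cell fraction of contacts
formed inside annotated TADs, and contact moments with an
independent-contacts baseline used to probe cooperativity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .imaging_synth import CellTrace
from .preprocess import ContactMatrix, distance_matrix

__all__ = [
    "BoundaryProfile",
    "TADAnnotation",
    "mean_distance_map",
    "boundary_score_profile",
    "detect_boundaries",
    "tad_contact_fraction",
    "ContactMoments",
    "contact_moments",
    "ensemble_agreement",
]


@dataclass
class BoundaryProfile:
    """Per-bin boundary score d_inter/d_intra; NaN where a full window is unavailable."""

    scores: np.ndarray
    window_bins: int


@dataclass
class TADAnnotation:
    """Ordered boundary bin indices partitioning [0, n_bins) into domains."""

    boundaries: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries.size and (
            self.boundaries[0] <= 0 or self.boundaries[-1] >= self.n_bins
        ):
            raise ValueError("boundaries must lie strictly inside (0, n_bins)")

    def domain_of(self) -> np.ndarray:
        """Domain index of every bin."""
        return np.searchsorted(self.boundaries, np.arange(self.n_bins), side="right")


def mean_distance_map(cells: list[CellTrace]) -> np.ndarray:
    """Entrywise mean distance over cells, ignoring missing probes."""
    if not cells:
        raise ValueError("need at least one cell")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries
        return np.nanmean(np.stack([distance_matrix(c) for c in cells]), axis=0)


def boundary_score_profile(mean_map: np.ndarray, window_bins: int = 2) -> BoundaryProfile:
    """Boundary score at every bin with complete upstream/downstream windows.

    At bin i with window w: U = [i-w, i), D = [i, i+w);
    d_inter = mean distance over U x D; d_intra = min(mean within-U pair
    distance, mean within-D); score = d_inter / d_intra.  Scores are NaN at
    the first and last w bins.  window_bins = 180 kb / bin size (2 at 90 kb).
    """
    m = np.asarray(mean_map, dtype=float)
    n = m.shape[0]
    w = window_bins
    if w < 2:
        raise ValueError("window_bins must be >= 2 (within-window pairs needed)")
    scores = np.full(n, np.nan)
    if 2 * w > n:
        warnings.warn("window exceeds map size; all scores undefined")
        return BoundaryProfile(scores=scores, window_bins=w)
    iu, ju = np.triu_indices(w, k=1)
    for i in range(w, n - w + 1):
        U = np.arange(i - w, i)
        D = np.arange(i, i + w)
        d_inter = float(np.mean(m[np.ix_(U, D)]))
        d_u = float(np.mean(m[U[iu], U[ju]]))
        d_d = float(np.mean(m[D[iu], D[ju]]))
        d_intra = min(d_u, d_d)
        if np.isfinite(d_inter) and np.isfinite(d_intra) and d_intra > 0:
            scores[i] = d_inter / d_intra
    return BoundaryProfile(scores=scores, window_bins=w)


def detect_boundaries(profile: BoundaryProfile, min_score: float = 1.2,
                      min_separation_bins: int = 2) -> TADAnnotation:
    """Local maxima of the score above ``min_score``, greedily pruned by separation."""
    s = profile.scores
    n = len(s)
    candidates = []
    for i in range(n):
        if not np.isfinite(s[i]) or s[i] < min_score:
            continue
        left = s[i - 1] if i > 0 and np.isfinite(s[i - 1]) else -np.inf
        right = s[i + 1] if i < n - 1 and np.isfinite(s[i + 1]) else -np.inf
        if s[i] >= left and s[i] >= right:
            candidates.append(i)
    # greedy: keep highest peaks first, enforce min separation
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -s[i]):
        if all(abs(i - j) >= min_separation_bins for j in kept):
            kept.append(i)
    return TADAnnotation(boundaries=np.sort(kept), n_bins=n)


def tad_contact_fraction(q: ContactMatrix | np.ndarray, tads: TADAnnotation,
                         min_separation: int = 2) -> float:
    """Fraction of contacts with both ends inside one domain.

    Contacts are counted over i < j with j - i >= ``min_separation`` (default
    excludes trivially adjacent contacts).  Returns NaN if there are no
    contacts at all.
    """
    entries = q.entries if isinstance(q, ContactMatrix) else np.asarray(q, dtype=float)
    n = entries.shape[0]
    dom = tads.domain_of()
    ii, jj = np.triu_indices(n, k=min_separation)
    c = entries[ii, jj]
    total = np.nansum(c)
    if total == 0:
        return float("nan")
    within = np.nansum(c[dom[ii] == dom[jj]])
    return float(within / total)


@dataclass
class ContactMoments:
    first: np.ndarray            # <Q_i> per feature index
    second: np.ndarray           # <Q_i Q_j> over sampled index pairs
    independent: np.ndarray      # <Q_i><Q_j> over the same pairs
    pair_indices: np.ndarray     # (n_pairs, 2) feature-index pairs


def contact_moments(vectors: np.ndarray, max_pairs: int | None = 20000,
                    seed: int = 0) -> ContactMoments:
    """First and second contact moments of an ensemble of contact vectors.

    ``vectors`` is (n_structures, n_features).  Second moments are computed
    over a random subsample of feature-index pairs (all pairs if ``max_pairs``
    is None or large enough).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (m >= 2, L) ensemble")
    first = X.mean(axis=0)
    L = X.shape[1]
    ii, jj = np.triu_indices(L, k=1)
    n_all = len(ii)
    if max_pairs is not None and max_pairs < n_all:
        rng = np.random.default_rng(seed)
        sel = rng.choice(n_all, size=max_pairs, replace=False)
        ii, jj = ii[sel], jj[sel]
    second = np.mean(X[:, ii] * X[:, jj], axis=0)
    independent = first[ii] * first[jj]
    return ContactMoments(first=first, second=second, independent=independent,
                          pair_indices=np.column_stack([ii, jj]))


def ensemble_agreement(moments_data: np.ndarray,
                       moments_model: np.ndarray) -> tuple[float, float]:
    """(Pearson r, mean absolute deviation) between two aligned moment sets."""
    a = np.asarray(moments_data, dtype=float)
    b = np.asarray(moments_model, dtype=float)
    if a.shape != b.shape:
        raise ValueError("moment sets are misaligned")
    if a.size < 3:
        raise ValueError("need at least 3 points")
    r = float(pearsonr(a, b).statistic)
    mad = float(np.mean(np.abs(a - b)))
    return r, mad
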