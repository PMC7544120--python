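"""The one-dimensional folding coordinate and baseline embeddings.

The two cell populations separate in the 2-D latent space of the embedding
VAE; a soft-margin linear SVM fit to the labeled embeddings defines a
decision boundary, and the folding coordinate of any structure is the signed
distance of its embedding from that boundary (WT side positive).  The
separation achieved is quantified by a histogram KL divergence between the
per-population coordinate distributions; PCA and K-means provide the
baselines the coordinate is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.svm import SVC

__all__ = [
    "FoldingCoordinateModel",
    "fit_separator",
    "coordinate_value",
    "misclassification_rate",
    "kl_divergence_discrete",
    "kl_divergence_1d",
    "PCAResult",
    "pca_projection",
    "kmeans_overlap",
]


@dataclass
class FoldingCoordinateModel:
    """Linear separator (w, b); coordinate(z) = (w.z + b)/||w||, WT mean positive."""

    w: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.linalg.norm(self.w) == 0:
            raise ValueError("separator weights must be non-zero")


def fit_separator(embeddings_a: np.ndarray, embeddings_b: np.ndarray,
                  C: float = 1.0) -> FoldingCoordinateModel:
    """Soft-margin linear SVM boundary between two labeled embedding sets.

    Set A is the WT-like population; the sign is fixed so its mean coordinate
    is positive.
    """
    a = np.asarray(embeddings_a, dtype=float)
    b = np.asarray(embeddings_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both embedding sets must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("embedding dimensions differ")
    X = np.vstack([a, b])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate embeddings: all points identical")
    y = np.concatenate([np.ones(len(a)), -np.ones(len(b))])
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    model = FoldingCoordinateModel(w=svm.coef_[0], b=float(svm.intercept_[0]))
    if np.mean(coordinate_value(model, a)) < 0:
        model = FoldingCoordinateModel(w=-model.w, b=-model.b)
    return model


def coordinate_value(model: FoldingCoordinateModel, z: np.ndarray) -> np.ndarray | float:
    """Signed distance from the boundary, (w.z + b)/||w||."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zz = np.atleast_2d(z)
    if zz.shape[1] != model.w.shape[0]:
        raise ValueError("embedding dimension mismatch")
    vals = (zz @ model.w + model.b) / np.linalg.norm(model.w)
    return float(vals[0]) if single else vals


def misclassification_rate(model: FoldingCoordinateModel,
                           embeddings_a: np.ndarray,
                           embeddings_b: np.ndarray) -> float:
    """Fraction of A below the boundary plus B above it, over all points."""
    ca = np.atleast_1d(coordinate_value(model, embeddings_a))
    cb = np.atleast_1d(coordinate_value(model, embeddings_b))
    wrong = int(np.sum(ca < 0)) + int(np.sum(cb > 0))
    return wrong / (len(ca) + len(cb))


def kl_divergence_discrete(p: np.ndarray, q: np.ndarray) -> float:
    """Exact KL(p || q) in nats for two discrete distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    mask = p > 0
    if np.any(q[mask] == 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_divergence_1d(samples_p: np.ndarray, samples_q: np.ndarray,
                     bins: int = 50) -> float:
    """Histogram KL(p || q) in nats on shared bins with 1-pseudo-count smoothing."""
    sp = np.asarray(samples_p, dtype=float)
    sq = np.asarray(samples_q, dtype=float)
    if sp.size == 0 or sq.size == 0:
        raise ValueError("samples must be non-empty")
    lo = min(sp.min(), sq.min())
    hi = max(sp.max(), sq.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    cp, _ = np.histogram(sp, bins=edges)
    cq, _ = np.histogram(sq, bins=edges)
    p = (cp + 1.0) / (cp.sum() + bins)
    q = (cq + 1.0) / (cq.sum() + bins)
    return kl_divergence_discrete(p, q)


@dataclass
class PCAResult:
    scores: np.ndarray
    component: np.ndarray
    explained_variance: float
    explained_variance_ratio: float


def pca_projection(vectors: np.ndarray) -> PCAResult:
    """First-principal-component scores of centered data (baseline embedding)."""
    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    return PCAResult(
        scores=scores,
        component=pca.components_[0],
        explained_variance=float(pca.explained_variance_[0]),
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
    )


def kmeans_overlap(vectors: np.ndarray, labels: np.ndarray, k: int = 10,
                   seed: int = 0) -> float:
    """K-means baseline: summed per-cluster minority mass between two cell types.

    overlap = sum_c min(n_A(c), n_B(c)) / N — zero when every cluster is pure,
    approaching 1/2 when both types are mixed evenly in every cluster.
    """
    X = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of points")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two cell-type labels required")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(X)
    overlap = 0
    for c in range(k):
        in_c = assign == c
        overlap += min(int(np.sum(in_c & (labels == uniq[0]))),
                       int(np.sum(in_c & (labels == uniq[1]))))
    return overlap / X.shape[0]
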