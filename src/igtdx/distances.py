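"""Feature-feature dissimilarity matrices under six metrics.

All metrics operate on the *columns* of the data matrix (features), never
on samples.  Available metrics:

``ED``
    Euclidean distance between feature vectors over samples.
``RD``
    One minus Pearson correlation; range [0, 2]; scale invariant but not a
    true metric (fails the triangle inequality).
``GD``
    Geodesic distance: shortest-path length on a symmetric k-nearest-
    neighbour graph over features with Euclidean edge weights (an
    ISOMAP-style estimate of intrinsic manifold distance).  Disconnected
    graphs (the "pinch problem") are bridged by single linkage: the
    globally closest inter-component feature pair is joined until one
    component remains.
``JD``
    Jensen-Shannon divergence between features normalized to probability
    mass functions over the samples; base-2 logs so values lie in [0, 1].
    (Only the square root of this quantity is a true metric; the
    divergence itself is returned by default.)
``WD``
    1-D Wasserstein (W2) distance between the empirical distributions of
    two features, computed from sorted columns as the root mean squared
    difference of order statistics (the quantile-function form of optimal
    transport on the line).
``TD``
    Tropical (max-plus / generalized Hilbert projective) distance:
    max_k(x_ki - x_kj) - min_k(x_ki - x_kj), the range of coordinate-wise
    differences; invariant to additive shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from .io import TabularDataset

METRICS = ("ED", "RD", "GD", "JD", "WD", "TD")

__all__ = [
    "METRICS", "DistanceMatrix", "compute_distance",
    "euclidean_distance", "one_minus_correlation", "geodesic_distance",
    "jensen_shannon_distance", "wasserstein_distance", "tropical_distance",
    "gaussian_w2_closed_form", "feature_pmf",
]


@dataclass
class DistanceMatrix:
    """Symmetric p x p feature dissimilarities under a named metric."""

    D: np.ndarray
    metric_name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.isfinite(D).all():
            raise ValueError("D contains non-finite entries")
        if np.abs(D - D.T).max(initial=0.0) > 1e-9:
            raise ValueError("D must be symmetric to 1e-9")
        # exact symmetry and clean diagonal for downstream ranking
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        if D.min() < -1e-12:
            raise ValueError("D must be nonnegative")
        self.D = np.maximum(D, 0.0)

    @property
    def p(self) -> int:
        return self.D.shape[0]

    def save(self, path) -> None:
        """Write the matrix as ``.npz`` (lossless) or delimited text (``.csv``/``.tsv``)."""
        from pathlib import Path

        path = Path(path)
        if path.suffix == ".npz":
            np.savez(path, D=self.D, metric_name=np.array(self.metric_name))
        elif path.suffix in (".csv", ".tsv"):
            np.savetxt(path, self.D, delimiter="," if path.suffix == ".csv" else "\t")
        else:
            raise ValueError("use .npz, .csv or .tsv")

    @classmethod
    def load(cls, path) -> "DistanceMatrix":
        from pathlib import Path

        path = Path(path)
        if path.suffix == ".npz":
            with np.load(path) as z:
                return cls(z["D"], str(z["metric_name"]))
        D = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else "\t")
        return cls(D, "NA")


def _as_matrix(X: TabularDataset | np.ndarray) -> np.ndarray:
    M = X.X if isinstance(X, TabularDataset) else np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if M.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if not np.isfinite(M).all():
        raise ValueError("input contains non-finite values")
    return M


def euclidean_distance(X: TabularDataset | np.ndarray) -> DistanceMatrix:
    """Euclidean distance between feature columns over samples."""
    M = _as_matrix(X)
    D = squareform(pdist(M.T, metric="euclidean"))
    return DistanceMatrix(D, "ED")


def one_minus_correlation(X: TabularDataset | np.ndarray) -> DistanceMatrix:
    """1 - Pearson correlation between feature columns; range [0, 2].

    Zero-variance features have undefined correlation; their distances to
    every other feature are set to 1 (the uncorrelated value) and a
    warning is emitted.
    """
    M = _as_matrix(X)
    sd = M.std(axis=0, ddof=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M.T)
    D = 1.0 - C
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s); "
            "their correlation distances are set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        D[degenerate, :] = 1.0
        D[:, degenerate] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 2.0)  # guard fp excursions outside [-1, 1] correlation
    return DistanceMatrix(D, "RD")


def _knn_graph_shortest_paths(E: np.ndarray, k: int) -> np.ndarray:
    """All-pairs shortest paths on a symmetric kNN graph with weights ``E``.

    An edge (i, j) exists if j is among i's k nearest neighbours or vice
    versa.  Disconnected components are bridged by repeatedly adding the
    single minimum-weight inter-component edge (single linkage).
    """
    p = E.shape[0]
    order = np.argsort(E, axis=1, kind="stable")
    # column 0 is the node itself (distance 0); ties with true 0-distance
    # neighbours are harmless: any k columns after self give a valid kNN set
    neigh = order[:, 1 : k + 1]
    rows = np.repeat(np.arange(p), k)
    cols = neigh.ravel()
    mask = np.zeros((p, p), dtype=bool)
    mask[rows, cols] = True
    mask |= mask.T

    n_comp, labels = connected_components(coo_matrix(mask), directed=False)
    while n_comp > 1:
        # global minimum-weight edge joining two different components
        inter = labels[:, None] != labels[None, :]
        W = np.where(inter, E, np.inf)
        i, j = np.unravel_index(np.argmin(W), W.shape)
        mask[i, j] = mask[j, i] = True
        labels[labels == labels[j]] = labels[i]
        n_comp -= 1

    graph = coo_matrix(np.where(mask, E, 0.0))
    D = dijkstra(graph.tocsr(), directed=False)
    return D


def geodesic_distance(X: TabularDataset | np.ndarray, k: int = 10) -> DistanceMatrix:
    """ISOMAP-style geodesic distance between features (see module docs)."""
    M = _as_matrix(X)
    p = M.shape[1]
    if not 1 <= k < p:
        raise ValueError(f"k must satisfy 1 <= k < p (got k={k}, p={p})")
    E = squareform(pdist(M.T, metric="euclidean"))
    D = _knn_graph_shortest_paths(E, k)
    return DistanceMatrix(D, "GD", {"k": k})


def feature_pmf(X: TabularDataset | np.ndarray) -> np.ndarray:
    """Normalize each feature column to a probability mass function.

    Plain sum-to-one normalization when all values are nonnegative;
    column-wise softmax as soon as any value in the matrix is negative
    (e.g. z-scored data).  An all-zero nonnegative column falls back to
    the uniform PMF with a warning.
    """
    M = _as_matrix(X)
    n = M.shape[0]
    if (M < 0).any():
        Z = M - M.max(axis=0, keepdims=True)
        expZ = np.exp(Z)
        P = expZ / expZ.sum(axis=0, keepdims=True)
    else:
        s = M.sum(axis=0, keepdims=True)
        zero = s[0] == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} all-zero column(s) replaced by uniform PMF",
                RuntimeWarning,
                stacklevel=2,
            )
        s = np.where(s == 0, 1.0, s)
        P = M / s
        P[:, zero] = 1.0 / n
    return P


def jensen_shannon_distance(
    X: TabularDataset | np.ndarray, sqrt: bool = False
) -> DistanceMatrix:
    """Jensen-Shannon divergence between feature PMFs, base-2 logs.

    D_ij = 1/2 KL(P_i || M) + 1/2 KL(P_j || M) with M = (P_i + P_j)/2;
    zero-mass terms contribute 0.  Bounded in [0, 1].  The divergence
    itself is returned by default; pass ``sqrt=True`` for its square
    root, which (unlike the divergence) satisfies the triangle
    inequality.
    """
    P = feature_pmf(X)
    # scipy's jensenshannon is sqrt(JS divergence) in nats; square and
    # rescale to base-2 so the value is the divergence in [0, 1]
    d = pdist(P.T, metric="jensenshannon")
    D = squareform(d) ** 2 / np.log(2.0)
    D = np.clip(D, 0.0, 1.0)
    if sqrt:
        D = np.sqrt(D)
    return DistanceMatrix(D, "JD", {"sqrt": sqrt})


def wasserstein_distance(X: TabularDataset | np.ndarray) -> DistanceMatrix:
    """1-D W2 distance between features from sorted columns.

    sqrt( (1/n) sum_k (x_(k)i - x_(k)j)^2 ) over order statistics x_(k):
    the quantile-function integral discretized at the n empirical
    quantiles, so a constant shift c yields exactly |c|.
    """
    M = _as_matrix(X)
    n = M.shape[0]
    S = np.sort(M, axis=0)
    D = squareform(pdist(S.T, metric="euclidean")) / np.sqrt(n)
    return DistanceMatrix(D, "WD")


def tropical_distance(X: TabularDataset | np.ndarray) -> DistanceMatrix:
    """Tropical distance: range of coordinate-wise differences."""
    M = _as_matrix(X)
    p = M.shape[1]
    D = np.empty((p, p))
    chunk = max(1, int(2**22 // (M.shape[0] * p + 1)))
    for s in range(0, p, chunk):
        e = min(s + chunk, p)
        diff = M[:, s:e, None] - M[:, None, :]  # (n, chunk, p)
        D[s:e, :] = diff.max(axis=0) - diff.min(axis=0)
    return DistanceMatrix(D, "TD")


def gaussian_w2_closed_form(
    mu_x: float, mu_y: float, sigma_x: float, sigma_y: float, rho: float
) -> float:
    """Squared W2 distance between two (jointly) Gaussian variables.

    Returns (mu_x - mu_y)^2 + (sigma_x - sigma_y)^2 + 2 sigma_x sigma_y (1 - rho).
    With rho = 1 (the comonotone coupling) this reduces to the marginal
    1-D W2^2, the large-sample limit of :func:`wasserstein_distance`.
    """
    if sigma_x < 0 or sigma_y < 0:
        raise ValueError("standard deviations must be nonnegative")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    return (mu_x - mu_y) ** 2 + (sigma_x - sigma_y) ** 2 + 2 * sigma_x * sigma_y * (1 - rho)


_DISPATCH = {
    "ED": euclidean_distance,
    "RD": one_minus_correlation,
    "JD": jensen_shannon_distance,
    "WD": wasserstein_distance,
    "TD": tropical_distance,
}


def compute_distance(
    X: TabularDataset | np.ndarray, metric: str, k: int = 10
) -> DistanceMatrix:
    """Compute the feature distance matrix under ``metric``.

    ``metric`` is one of ``ED, RD, GD, JD, WD, TD``; ``k`` is the
    neighbour count for the geodesic metric and ignored otherwise.
    """
    if metric == "GD":
        return geodesic_distance(X, k=k)
    if metric not in _DISPATCH:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return _DISPATCH[metric](X)
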