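"""Six synthetic dataset generators, one aligned with each distance metric.

Every generator emits ``n = 200`` samples and ``p = 2500`` features by
default: the first ``p_signal = 100`` columns carry the structured signal
and the remaining columns are label-independent Gaussian noise, emulating
high-dimensional omics-style tables where the discriminative structure is
confined to a small feature block.

Models (name -> structure -> aligned metric):

``euclidean``
    i.i.d. Gaussian signal N(0, 2 I) with logistic labels,
    logit P(Y=1) = X . beta, beta ~ N(2.5 1, I)  ->  ED.
``correlation``
    Toeplitz-correlated Gaussian signal (Sigma_jk = rho^|j-k|, rho=0.95)
    with a monotone coefficient grid beta = (1/100, ..., 1) and logit
    scale 3  ->  RD.
``geodesic``
    Swiss-roll manifold points embedded in 100 dims by a seeded rotation;
    labels from a median split of the kNN-graph shortest-path (geodesic)
    distance to a reference sample  ->  GD.
``js``
    Class-conditional Dirichlet compositions on the 99-simplex
    (alpha0 = 0.1, alpha1 = 5)  ->  JD.
``wasserstein``
    Sorted vectors of 100 Gaussian draws (N(0,1) vs N(1,1)) relabelled by
    a median split of the cumulative-sum W1 distance to the class-0 mean
    quantile template  ->  WD.
``tropical``
    Five random contiguous segments of per-sample plateau levels
    U(-1, 1); two segments shifted by +/-Delta for class 1; small
    within-segment jitter; optional column centering that removes the
    Euclidean/correlation cues while leaving the (shift-invariant)
    tropical distances untouched  ->  TD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import cholesky, qr, toeplitz
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from .io import TabularDataset

MODELS = ("euclidean", "correlation", "geodesic", "js", "wasserstein", "tropical")

__all__ = ["MODELS", "SimSpec", "simulate"]


@dataclass
class SimSpec:
    """Parameters of one simulated dataset.

    Defaults are the study conditions: n=200 samples, p=2500 features of
    which the first 100 carry signal.  Model-specific parameters hold the
    stated values (rho=0.95; Dirichlet alpha0=0.1, alpha1=5; tropical
    S=5 segments, Delta=1.75 in [1.5, 2.0], sigma_seg=0.10, sigma_n=0.01,
    column centering on; geodesic neighbour count k=10).
    """

    model_name: str = "euclidean"
    n: int = 200
    p: int = 2500
    p_signal: int = 100
    seed: int = 0
    rho: float = 0.95
    alpha0: float = 0.1
    alpha1: float = 5.0
    segments: int = 5
    delta: float = 1.75
    sigma_seg: float = 0.10
    sigma_noise: float = 0.01
    center_columns: bool = True
    geodesic_k: int = 10

    def __post_init__(self) -> None:
        if self.model_name not in MODELS:
            raise ValueError(f"model_name must be one of {MODELS}")
        if self.p_signal > self.p:
            raise ValueError("p_signal must not exceed p")
        if self.n < 2:
            raise ValueError("need n >= 2")
        if min(self.sigma_seg, self.sigma_noise, self.alpha0, self.alpha1) <= 0:
            raise ValueError("scale/concentration parameters must be positive")
        if not 1.5 <= self.delta <= 2.0:
            raise ValueError("delta must lie in [1.5, 2.0]")
        if self.segments > self.p_signal:
            raise ValueError("more segments than signal features")


def _finish(
    spec: SimSpec,
    X_signal: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    metadata: dict[str, Any] | None = None,
) -> TabularDataset:
    """Append the noise block and wrap as a TabularDataset."""
    n, ps = X_signal.shape
    noise = rng.standard_normal((n, spec.p - ps)) * noise_sd
    X = np.hstack([X_signal, noise])
    md = {"sim_spec": spec, **(metadata or {})}
    return TabularDataset(
        X=X,
        y=y,
        feature_names=[f"f{j + 1}" for j in range(spec.p)],
        sample_ids=[f"s{i + 1}" for i in range(n)],
        metadata=md,
    )


def _simulate_euclidean(spec: SimSpec, rng: np.random.Generator) -> TabularDataset:
    ps = spec.p_signal
    X = rng.standard_normal((spec.n, ps)) * np.sqrt(2.0)  # N(0, 2 I)
    beta = 2.5 + rng.standard_normal(ps)
    logits = X @ beta
    prob = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(spec.n) < prob).astype(int)
    return _finish(spec, X, y, rng, metadata={"beta": beta})


def _simulate_correlation(spec: SimSpec, rng: np.random.Generator) -> TabularDataset:
    ps = spec.p_signal
    Sigma = toeplitz(spec.rho ** np.arange(ps))
    L = cholesky(Sigma, lower=True)
    X = rng.standard_normal((spec.n, ps)) @ L.T
    beta = np.arange(1, ps + 1) / ps  # (1/100, 2/100, ..., 1)
    logits = 3.0 * (X @ beta)
    prob = 1.0 / (1.0 + np.exp(-logits))
    y = (rng.random(spec.n) < prob).astype(int)
    return _finish(spec, X, y, rng, metadata={"beta": beta})


def _sample_graph_geodesic(P: np.ndarray, k: int, source: int = 0) -> np.ndarray:
    """Shortest-path distance from ``source`` on a symmetric kNN sample graph."""
    n = P.shape[0]
    E = squareform(pdist(P))
    order = np.argsort(E, axis=1, kind="stable")
    neigh = order[:, 1 : k + 1]
    mask = np.zeros((n, n), dtype=bool)
    mask[np.repeat(np.arange(n), k), neigh.ravel()] = True
    mask |= mask.T
    n_comp, labels = connected_components(coo_matrix(mask), directed=False)
    while n_comp > 1:  # single-linkage bridging, as for feature graphs
        inter = labels[:, None] != labels[None, :]
        W = np.where(inter, E, np.inf)
        i, j = np.unravel_index(np.argmin(W), W.shape)
        mask[i, j] = mask[j, i] = True
        labels[labels == labels[j]] = labels[i]
        n_comp -= 1
    graph = coo_matrix(np.where(mask, E, 0.0)).tocsr()
    return dijkstra(graph, directed=False, indices=source)


def _simulate_geodesic(spec: SimSpec, rng: np.random.Generator) -> TabularDataset:
    ps = spec.p_signal
    # classical Swiss roll: (t cos t, h, t sin t)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=spec.n)
    h = rng.uniform(0.0, 21.0, size=spec.n)
    roll = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    # zero-pad to ps dims, then a fixed seeded random rotation (isometry)
    G = rng.standard_normal((ps, ps))
    Qm, Rm = qr(G)
    Qm *= np.sign(np.diag(Rm))  # deterministic sign convention
    padded = np.zeros((spec.n, ps))
    padded[:, :3] = roll
    X = padded @ Qm.T
    f = _sample_graph_geodesic(X, spec.geodesic_k, source=0)
    tau = np.median(f)
    y = (f > tau).astype(int)  # ties at the median fall to class 0
    return _finish(spec, X, y, rng, metadata={"f": f, "tau": float(tau)})


def _simulate_js(spec: SimSpec, rng: np.random.Generator) -> TabularDataset:
    ps = spec.p_signal
    y = (rng.random(spec.n) < 0.5).astype(int)
    X = np.empty((spec.n, ps))
    n0 = int((y == 0).sum())
    X[y == 0] = rng.dirichlet(np.full(ps, spec.alpha0), size=n0)
    X[y == 1] = rng.dirichlet(np.full(ps, spec.alpha1), size=spec.n - n0)
    return _finish(spec, X, y, rng)


def _simulate_wasserstein(spec: SimSpec, rng: np.random.Generator) -> TabularDataset:
    ps = spec.p_signal
    y_gen = (rng.random(spec.n) < 0.5).astype(int)
    if (y_gen == 0).sum() == 0:
        raise RuntimeError("no class-0 draws to form the template; reseed")
    mu = y_gen.astype(float)  # 0 or 1
    draws = rng.standard_normal((spec.n, ps)) + mu[:, None]
    X = np.sort(draws, axis=1)  # each row a quantile vector
    T = X[y_gen == 0].mean(axis=0)
    w1 = np.abs(np.cumsum(X - T, axis=1)).sum(axis=1)
    tau = np.median(w1)
    y = (w1 > tau).astype(int)  # ties at the median fall to class 0
    return _finish(
        spec, X, y, rng,
        metadata={"y_generating": y_gen, "template": T, "w1": w1, "tau": float(tau)},
    )


def _simulate_tropical(spec: SimSpec, rng: np.random.Generator) -> TabularDataset:
    ps, S = spec.p_signal, spec.segments
    # near-equal contiguous blocks of a shuffled index set
    idx = rng.permutation(ps)
    bounds = np.linspace(0, ps, S + 1).round().astype(int)
    seg_of = np.empty(ps, dtype=int)
    for s in range(S):
        seg_of[idx[bounds[s] : bounds[s + 1]]] = s
    s_plus, s_minus = rng.choice(S, size=2, replace=False)

    y = (rng.random(spec.n) < 0.5).astype(int)
    v = rng.uniform(-1.0, 1.0, size=(spec.n, S))
    shift = np.zeros(S)
    shift[s_plus] = spec.delta
    shift[s_minus] = -spec.delta
    levels = v + np.outer(y, shift)
    X = levels[:, seg_of] + rng.normal(0.0, spec.sigma_seg, size=(spec.n, ps))
    X_raw = X.copy()
    if spec.center_columns:
        X = X - X.mean(axis=0, keepdims=True)
    return _finish(
        spec, X, y, rng, noise_sd=spec.sigma_noise,
        metadata={
            "segment_of": seg_of,
            "s_plus": int(s_plus),
            "s_minus": int(s_minus),
            "X_signal_uncentered": X_raw,
        },
    )


_GEN = {
    "euclidean": _simulate_euclidean,
    "correlation": _simulate_correlation,
    "geodesic": _simulate_geodesic,
    "js": _simulate_js,
    "wasserstein": _simulate_wasserstein,
    "tropical": _simulate_tropical,
}


def simulate(spec: SimSpec | str, **overrides: Any) -> TabularDataset:
    """Generate a dataset from a :class:`SimSpec` (or a model name).

    ``simulate("js", seed=1)`` is shorthand for
    ``simulate(SimSpec(model_name="js", seed=1))``.  Exactly reproducible
    for a given spec and seed.
    """
    if isinstance(spec, str):
        spec = SimSpec(model_name=spec, **overrides)
    elif overrides:
        raise TypeError("pass overrides only with a model name, not a full SimSpec")
    rng = np.random.default_rng(spec.seed)
    return _GEN[spec.model_name](spec, rng)
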