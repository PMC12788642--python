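"""Rank matrices, the IGTD swap optimizer, and pseudo-image rendering.

The converter assigns each of the p features of a table to one pixel of an
Nr x Nc grid (Nr * Nc = p) so that the ascending *ranks* of pairwise
feature distances match the ranks of pairwise pixel distances.  The
objective is

    err(R, Q) = sum_{i > j} (r_ij - q_ij)^2

over the lower triangle, where R holds feature-distance ranks (under any
metric) and Q holds Euclidean pixel-distance ranks for the row-major
grid.  Minimization proceeds by synchronized row/column swaps of R
(transpositions of the feature order), each candidate evaluated by an
O(p) incremental update rather than a full recomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix, compute_distance
from .io import PseudoImageSet, TabularDataset

__all__ = [
    "RankMatrix", "ImageLayout", "rank_matrix", "pixel_rank_matrix",
    "igtd_error", "swap_delta", "optimize_layout", "apply_layout",
    "reconstruct_table", "convert",
]


@dataclass
class RankMatrix:
    """Symmetric integer matrix of ascending pairwise-distance ranks.

    Off-diagonal entries are the ranks 1..p(p-1)/2 of the lower-triangle
    distances (each rank used exactly once); the diagonal is zero.
    ``grid_shape`` is set when the matrix ranks pixel distances.
    """

    R: np.ndarray
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.R)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("rank matrix must be square")
        if (np.diag(R) != 0).any():
            raise ValueError("diagonal must be zero")
        if (R != R.T).any():
            raise ValueError("rank matrix must be symmetric")
        p = R.shape[0]
        tril = R[np.tril_indices(p, -1)]
        m = p * (p - 1) // 2
        if m and not np.array_equal(np.sort(tril), np.arange(1, m + 1)):
            raise ValueError("lower-triangle ranks must be a permutation of 1..p(p-1)/2")
        self.R = R.astype(np.int64)

    @property
    def p(self) -> int:
        return self.R.shape[0]


def _rank_from_square(D: np.ndarray) -> np.ndarray:
    """Ordinal ranks of the lower-triangle distances, symmetrized.

    Ties are broken by lower-triangle scan order (row-major over i > j),
    which makes the ranking a bijection onto 1..p(p-1)/2.
    """
    p = D.shape[0]
    ii, jj = np.tril_indices(p, -1)
    d = D[ii, jj]
    order = np.argsort(d, kind="stable")
    ranks = np.empty(d.shape[0], dtype=np.int64)
    ranks[order] = np.arange(1, d.shape[0] + 1)
    R = np.zeros((p, p), dtype=np.int64)
    R[ii, jj] = ranks
    R[jj, ii] = ranks
    return R


def rank_matrix(D: DistanceMatrix | np.ndarray) -> RankMatrix:
    """Rank matrix R of a feature distance matrix (ascending, ordinal)."""
    M = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    return RankMatrix(_rank_from_square(M))


def pixel_rank_matrix(grid_shape: tuple[int, int]) -> RankMatrix:
    """Rank matrix Q of Euclidean distances between row-major grid pixels.

    Q is always Euclidean regardless of the feature metric: the target
    image grid is an inherently Euclidean space.
    """
    nr, nc = grid_shape
    if nr < 1 or nc < 1 or nr * nc < 2:
        raise ValueError("grid must contain at least 2 pixels")
    rr, cc = np.divmod(np.arange(nr * nc), nc)
    coords = np.column_stack([rr, cc]).astype(float)
    E = squareform(pdist(coords, metric="euclidean"))
    return RankMatrix(_rank_from_square(E), grid_shape=(nr, nc))


def igtd_error(R: RankMatrix | np.ndarray, Q: RankMatrix | np.ndarray) -> int:
    """Lower-triangle sum of squared rank differences between R and Q."""
    A = R.R if isinstance(R, RankMatrix) else np.asarray(R)
    B = Q.R if isinstance(Q, RankMatrix) else np.asarray(Q)
    if A.shape != B.shape:
        raise ValueError("R and Q must have the same shape")
    ii, jj = np.tril_indices(A.shape[0], -1)
    diff = A[ii, jj].astype(np.int64) - B[ii, jj].astype(np.int64)
    return int((diff * diff).sum())


def swap_delta(R: np.ndarray, Q: np.ndarray, a: int, b: int) -> int:
    """Exact change in err(R, Q) if rows+columns a and b of R are swapped.

    Uses the identity
    ``delta = 2 * sum_{k != a,b} (R[b,k]-R[a,k]) * (Q[b,k]-Q[a,k])``,
    an O(p) evaluation in integer arithmetic.
    """
    R = np.asarray(R, dtype=np.int64)
    Q = np.asarray(Q, dtype=np.int64)
    dr = R[b] - R[a]
    dq = Q[b] - Q[a]
    total = int(np.dot(dr, dq))
    total -= int(dr[a]) * int(dq[a]) + int(dr[b]) * int(dq[b])
    return 2 * total


@dataclass
class ImageLayout:
    """A bijective feature -> pixel assignment on an Nr x Nc grid.

    ``feature_to_pixel[j]`` is the row-major pixel index of feature j.
    ``error_trace`` records err(R', Q) at start and after every accepted
    swap (non-increasing).  ``scale_min``/``scale_max`` hold the
    per-feature intensity scaling fitted by :func:`apply_layout`.
    """

    feature_to_pixel: np.ndarray
    grid_shape: tuple[int, int]
    error_trace: list[int] = field(default_factory=list)
    metric_name: str = ""
    seed: int = 0
    scale_min: np.ndarray | None = None
    scale_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        perm = np.asarray(self.feature_to_pixel, dtype=np.int64)
        p = perm.shape[0]
        if not np.array_equal(np.sort(perm), np.arange(p)):
            raise ValueError("feature_to_pixel must be a bijection on 0..p-1")
        if np.any(np.diff(self.error_trace) > 0):
            raise ValueError("error_trace must be non-increasing")
        self.feature_to_pixel = perm

    @property
    def p(self) -> int:
        return self.feature_to_pixel.shape[0]

    @property
    def layout_id(self) -> str:
        nr, nc = self.grid_shape
        return f"{self.metric_name or 'NA'}-{nr}x{nc}-seed{self.seed}"

    def to_json(self, path: str | Path) -> None:
        d: dict[str, Any] = {
            "feature_to_pixel": self.feature_to_pixel.tolist(),
            "grid_shape": list(self.grid_shape),
            "error_trace": [int(e) for e in self.error_trace],
            "metric_name": self.metric_name,
            "seed": self.seed,
            "scale_min": None if self.scale_min is None else self.scale_min.tolist(),
            "scale_max": None if self.scale_max is None else self.scale_max.tolist(),
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "ImageLayout":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_to_pixel=np.array(d["feature_to_pixel"], dtype=np.int64),
            grid_shape=tuple(d["grid_shape"]),
            error_trace=d["error_trace"],
            metric_name=d.get("metric_name", ""),
            seed=d.get("seed", 0),
            scale_min=None if d["scale_min"] is None else np.array(d["scale_min"]),
            scale_max=None if d["scale_max"] is None else np.array(d["scale_max"]),
        )


def _fallback_grid(p: int) -> tuple[int, int]:
    nr = int(np.sqrt(p))
    while nr > 1 and p % nr:
        nr -= 1
    return (nr, p // nr)


def optimize_layout(
    R: RankMatrix,
    Q: RankMatrix,
    max_steps: int = 3000,
    stall_limit: int = 200,
    seed: int = 0,
    cooldown: int | None = None,
    metric_name: str = "",
) -> ImageLayout:
    """Minimize err(R', Q) over synchronized row/column permutations of R.

    Search policy: at each iteration pick the position with the largest
    error contribution among those not picked within the last ``cooldown``
    iterations (default p // 2), evaluate swapping it against every other
    position via the O(p) incremental update, and accept the swap with the
    largest error reduction (ties: smallest partner index).  The accepted
    swap's delta is re-evaluated in exact integer arithmetic, so the
    error trace is integer-exact.  Terminates after ``max_steps``
    iterations or ``stall_limit`` consecutive iterations without an
    accepted swap.  Deterministic given inputs.
    """
    if R.p != Q.p:
        raise ValueError("R and Q must have the same size")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    p = R.p
    if cooldown is None:
        cooldown = p // 2
    cooldown = min(cooldown, p - 1)  # at least one candidate must stay eligible

    Ri = R.R.copy()  # int64 current R'
    Qi = Q.R
    Rf = Ri.astype(np.float64)
    Qf = Qi.astype(np.float64)
    rq = (Rf * Qf).sum(axis=1)  # rowwise sum of R*Q products
    contrib = ((Rf - Qf) ** 2).sum(axis=1)
    pos_to_feature = np.arange(p)

    err = igtd_error(Ri, Qi)
    trace = [err]
    last_picked = np.full(p, -(10**9), dtype=np.int64)
    stall = 0

    for step in range(max_steps):
        eligible = (step - last_picked) > cooldown
        if not eligible.any():
            eligible[:] = True
        cand = np.flatnonzero(eligible)
        a = int(cand[np.argmax(contrib[cand])])
        last_picked[a] = step

        Ra, Qa = Rf[a], Qf[a]
        # delta(b)/2 = rq[b] + rq[a] - R[b]. Q[a] - Q[b] . R[a]
        #              - R[b,a] Q[b,a] - R[a,b] Q[a,b]     (k = a, b excluded)
        half = rq + rq[a] - Rf @ Qa - Qf @ Ra - Rf[:, a] * Qf[:, a] - Ra * Qa
        half[a] = 0.0

        b = int(np.argmin(half))  # ties: smallest partner index
        if b == a or half[b] >= 0.0:
            stall += 1
            if stall >= stall_limit:
                break
            continue
        delta = swap_delta(Ri, Qi, a, b)  # exact integer re-evaluation
        if delta >= 0:
            stall += 1
            if stall >= stall_limit:
                break
            continue

        # apply the swap of positions a and b (rows then columns)
        for Mx in (Ri, Rf):
            Mx[[a, b], :] = Mx[[b, a], :]
            Mx[:, [a, b]] = Mx[:, [b, a]]
        pos_to_feature[[a, b]] = pos_to_feature[[b, a]]

        # refresh cached row statistics (O(p) rows touched at cols a and b)
        rq = (Rf * Qf).sum(axis=1)
        contrib = ((Rf - Qf) ** 2).sum(axis=1)

        err += delta
        trace.append(err)
        stall = 0

    feature_to_pixel = np.empty(p, dtype=np.int64)
    feature_to_pixel[pos_to_feature] = np.arange(p)
    return ImageLayout(
        feature_to_pixel=feature_to_pixel,
        grid_shape=Q.grid_shape or _fallback_grid(p),
        error_trace=trace,
        metric_name=metric_name,
        seed=seed,
    )


def apply_layout(ds: TabularDataset, layout: ImageLayout) -> PseudoImageSet:
    """Render one grayscale pseudo-image per sample under ``layout``.

    Each feature is min-max scaled to [0, 1] over the samples (constant
    features map to 0.5) and written to its assigned pixel.  The fitted
    scaling is stored on the layout so images are invertible via
    :func:`reconstruct_table`.
    """
    nr, nc = layout.grid_shape
    if ds.p_features != nr * nc:
        raise ValueError(
            f"p_features={ds.p_features} does not fill the {nr}x{nc} grid"
        )
    lo = ds.X.min(axis=0)
    hi = ds.X.max(axis=0)
    span = hi - lo
    const = span == 0
    span = np.where(const, 1.0, span)
    scaled = (ds.X - lo) / span
    scaled[:, const] = 0.5
    layout.scale_min, layout.scale_max = lo, hi

    flat = np.empty_like(scaled)
    flat[:, layout.feature_to_pixel] = scaled
    images = flat.reshape(ds.n_samples, nr, nc)
    return PseudoImageSet(
        images=images, y=ds.y, layout_id=layout.layout_id, sample_ids=ds.sample_ids
    )


def reconstruct_table(imgs: PseudoImageSet, layout: ImageLayout) -> np.ndarray:
    """Invert :func:`apply_layout`: recover the original X matrix.

    Constant features (scale_min == scale_max) are restored to their
    stored constant value.
    """
    if layout.scale_min is None or layout.scale_max is None:
        raise ValueError("layout has no fitted intensity scaling")
    flat = imgs.images.reshape(imgs.images.shape[0], -1)
    scaled = flat[:, layout.feature_to_pixel]
    span = layout.scale_max - layout.scale_min
    const = span == 0
    X = scaled * np.where(const, 0.0, span) + layout.scale_min
    X[:, const] = layout.scale_min[const]
    return X


def convert(
    ds: TabularDataset,
    metric: str = "ED",
    grid_shape: tuple[int, int] | None = None,
    max_steps: int = 3000,
    stall_limit: int = 200,
    seed: int = 0,
    k: int = 10,
) -> tuple[ImageLayout, PseudoImageSet]:
    """End-to-end conversion: distances -> ranks -> optimize -> images.

    The layout is fit on the full dataset without labels (the transform is
    unsupervised) and can be reused across cross-validation folds.
    """
    if grid_shape is None:
        nr = int(round(np.sqrt(ds.p_features)))
        if nr * nr != ds.p_features:
            raise ValueError("p is not a perfect square; pass grid_shape explicitly")
        grid_shape = (nr, nr)
    D = compute_distance(ds, metric, k=k)
    R = rank_matrix(D)
    Q = pixel_rank_matrix(grid_shape)
    layout = optimize_layout(
        R, Q, max_steps=max_steps, stall_limit=stall_limit, seed=seed,
        metric_name=metric,
    )
    imgs = apply_layout(ds, layout)
    return layout, imgs
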