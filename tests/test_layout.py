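"""Rank construction, the swap optimizer, and image rendering."""

from itertools import permutations

import numpy as np
import pytest

from igtdx.io import TabularDataset
from igtdx.layout import (
    ImageLayout,
    apply_layout,
    convert,
    igtd_error,
    optimize_layout,
    pixel_rank_matrix,
    rank_matrix,
    reconstruct_table,
    swap_delta,
)


def _random_distance(rng, p):
    D = np.abs(rng.normal(size=(p, p)))
    D = D + D.T
    np.fill_diagonal(D, 0.0)
    return D


def brute_force_optimum(R, Q):
    """Minimum err over all p! synchronized permutations (oracle)."""
    p = R.shape[0]
    return min(
        igtd_error(R[list(pm)][:, list(pm)], Q) for pm in permutations(range(p))
    )


# ----------------------------------------------------------------- ranks

def test_rank_matrix_orders_three_pairs():
    D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    R = rank_matrix(D).R
    assert R[1, 0] == 1 and R[2, 0] == 2 and R[2, 1] == 3
    assert (R == R.T).all() and (np.diag(R) == 0).all()


def test_rank_matrix_tie_break_by_scan_order():
    D = np.ones((3, 3)) - np.eye(3)  # all distances equal
    R = rank_matrix(D).R
    # lower-triangle scan order (1,0), (2,0), (2,1) receives ranks 1, 2, 3
    assert (R[1, 0], R[2, 0], R[2, 1]) == (1, 2, 3)


def test_rank_matrix_random_is_valid(rng):
    R = rank_matrix(_random_distance(rng, 7)).R
    assert (R == R.T).all() and (np.diag(R) == 0).all()
    tri = R[np.tril_indices(7, -1)]
    assert sorted(tri) == list(range(1, 22))


def test_pixel_ranks_single_pair():
    assert pixel_rank_matrix((1, 2)).R[1, 0] == 1


def test_pixel_ranks_2x2_diagonals_largest():
    Q = pixel_rank_matrix((2, 2)).R
    # diagonal pixel pairs (0,3) and (1,2) at distance sqrt(2) rank above
    # the four side pairs at distance 1
    assert {Q[3, 0], Q[2, 1]} == {5, 6}
    assert {Q[1, 0], Q[2, 0], Q[3, 1], Q[3, 2]} == {1, 2, 3, 4}


def test_pixel_ranks_transpose_symmetry():
    # transposing the grid permutes pixels but preserves the distance
    # geometry; ranks agree up to permutation within tied distances
    nr, nc = 2, 3
    Q1 = pixel_rank_matrix((nr, nc)).R
    Q2 = pixel_rank_matrix((nc, nr)).R
    rr, cc = np.divmod(np.arange(nr * nc), nc)
    remap = cc * nr + rr
    Q2r = Q2[np.ix_(remap, remap)]
    from scipy.spatial.distance import pdist, squareform

    coords = np.column_stack([rr, cc]).astype(float)
    E = squareform(pdist(coords))
    ii, jj = np.tril_indices(nr * nc, -1)
    for d in np.unique(E[ii, jj]):
        grp = E[ii, jj] == d
        assert set(Q1[ii, jj][grp]) == set(Q2r[ii, jj][grp])


# ----------------------------------------------------------------- error

def test_error_examples():
    Q = pixel_rank_matrix((1, 3)).R
    assert igtd_error(Q, Q) == 0
    R = np.array([[0, 1], [1, 0]])
    assert igtd_error(R, R) == 0
    # lower-triangle ranks (1,2,3) vs (3,2,1): (1-3)^2 + 0 + (3-1)^2 = 8
    A = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
    B = np.array([[0, 3, 2], [3, 0, 1], [2, 1, 0]])
    assert igtd_error(A, B) == 8
    with pytest.raises(ValueError):
        igtd_error(A, R)


def test_swap_delta_equals_full_recomputation(rng):
    """Incremental O(p) swap evaluation is integer-exact on 100 instances."""
    for _ in range(100):
        p = int(rng.integers(4, 11))
        R = rank_matrix(_random_distance(rng, p)).R
        Q = rank_matrix(_random_distance(rng, p)).R
        a, b = rng.choice(p, size=2, replace=False)
        perm = np.arange(p)
        perm[[a, b]] = perm[[b, a]]
        Rp = R[perm][:, perm]
        assert igtd_error(Rp, Q) - igtd_error(R, Q) == swap_delta(R, Q, a, b)


# ------------------------------------------------------------- optimizer

def test_optimizer_identity_when_already_optimal():
    Q = pixel_rank_matrix((2, 3))
    lay = optimize_layout(Q, Q, max_steps=50, stall_limit=10)
    assert lay.error_trace == [0]
    assert (lay.feature_to_pixel == np.arange(6)).all()


def test_optimizer_recovers_single_transposition():
    # R built by transposing two grid positions of Q; the greedy search
    # undoes it within two iterations
    Q = pixel_rank_matrix((2, 2))
    perm = np.array([1, 0, 2, 3])
    from igtdx.layout import RankMatrix

    R = RankMatrix(Q.R[perm][:, perm])
    lay = optimize_layout(R, Q, max_steps=2, stall_limit=2)
    assert lay.error_trace[-1] == 0
    assert len(lay.error_trace) <= 3  # initial err + at most 2 swaps
    assert (lay.feature_to_pixel == perm).all()


@pytest.mark.parametrize("p,grid", [(4, (2, 2)), (6, (2, 3))])
def test_optimizer_bounded_by_brute_force(p, grid, rng):
    Q = pixel_rank_matrix(grid)
    for _ in range(3):
        R = rank_matrix(_random_distance(rng, p))
        best = brute_force_optimum(R.R, Q.R)
        lay = optimize_layout(R, Q, max_steps=300, stall_limit=60)
        assert best <= lay.error_trace[-1] <= lay.error_trace[0]


def test_optimum_invariant_to_feature_preshuffle(rng):
    """The brute-force minimum does not depend on R's initial order."""
    Q = pixel_rank_matrix((2, 2)).R
    R = rank_matrix(_random_distance(rng, 4)).R
    perm = rng.permutation(4)
    assert brute_force_optimum(R, Q) == brute_force_optimum(R[perm][:, perm], Q)


def test_optimizer_trace_strictly_decreasing(rng):
    R = rank_matrix(_random_distance(rng, 9))
    Q = pixel_rank_matrix((3, 3))
    lay = optimize_layout(R, Q, max_steps=200, stall_limit=50)
    trace = np.array(lay.error_trace)
    assert (np.diff(trace) < 0).all() or len(trace) == 1
    # final error is consistent with the returned permutation
    feat_at_pos = np.argsort(lay.feature_to_pixel)
    assert igtd_error(R.R[feat_at_pos][:, feat_at_pos], Q.R) == trace[-1]


def test_optimizer_deterministic(rng):
    R = rank_matrix(_random_distance(rng, 8))
    Q = pixel_rank_matrix((2, 4))
    a = optimize_layout(R, Q, max_steps=100, stall_limit=30, seed=5)
    b = optimize_layout(R, Q, max_steps=100, stall_limit=30, seed=5)
    assert (a.feature_to_pixel == b.feature_to_pixel).all()
    assert a.error_trace == b.error_trace


# ---------------------------------------------------------------- images

def _dataset(rng, n, p):
    return TabularDataset(
        X=rng.normal(size=(n, p)),
        y=(np.arange(n) % 2),
        feature_names=[f"f{j}" for j in range(p)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


def test_apply_identity_layout_row_grid(rng):
    ds = _dataset(rng, 4, 5)
    lay = ImageLayout(feature_to_pixel=np.arange(5), grid_shape=(1, 5))
    imgs = apply_layout(ds, lay)
    lo, hi = ds.X.min(axis=0), ds.X.max(axis=0)
    assert np.allclose(imgs.images[:, 0, :], (ds.X - lo) / (hi - lo))


def test_apply_layout_round_trip(rng):
    ds = _dataset(rng, 10, 12)
    lay = ImageLayout(feature_to_pixel=rng.permutation(12), grid_shape=(3, 4))
    imgs = apply_layout(ds, lay)
    assert np.abs(reconstruct_table(imgs, lay) - ds.X).max() < 1e-9


def test_apply_layout_constant_feature_and_duplicates(rng):
    ds = _dataset(rng, 6, 4)
    ds.X[:, 1] = 7.0  # constant feature -> intensity 0.5
    ds.X[3] = ds.X[2]  # duplicate rows -> identical images
    lay = ImageLayout(feature_to_pixel=np.arange(4), grid_shape=(2, 2))
    imgs = apply_layout(ds, lay)
    px = np.flatnonzero(lay.feature_to_pixel == 1)[0]
    assert np.all(imgs.images.reshape(6, -1)[:, 1] == 0.5)
    assert np.array_equal(imgs.images[2], imgs.images[3])
    X = reconstruct_table(imgs, lay)
    assert np.allclose(X[:, 1], 7.0)


def test_apply_layout_shape_mismatch(rng):
    ds = _dataset(rng, 4, 5)
    lay = ImageLayout(feature_to_pixel=np.arange(4), grid_shape=(2, 2))
    with pytest.raises(ValueError):
        apply_layout(ds, lay)


def test_layout_json_round_trip(tmp_path, rng):
    ds = _dataset(rng, 8, 9)
    lay, imgs = convert(ds, metric="ED", grid_shape=(3, 3), max_steps=50, stall_limit=10)
    path = tmp_path / "layout.json"
    lay.to_json(path)
    lay2 = ImageLayout.from_json(path)
    assert (lay2.feature_to_pixel == lay.feature_to_pixel).all()
    assert lay2.error_trace == lay.error_trace
    assert np.allclose(lay2.scale_min, lay.scale_min)
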