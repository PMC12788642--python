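"""Metric definitions against hand values and a double-loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igtdx.distances import (
    METRICS,
    compute_distance,
    euclidean_distance,
    feature_pmf,
    gaussian_w2_closed_form,
    geodesic_distance,
    jensen_shannon_distance,
    one_minus_correlation,
    tropical_distance,
    wasserstein_distance,
)

from conftest import naive_metric


# ------------------------------------------------------------- hand values

def test_euclidean_hand_values():
    # features (0,0) and (3,4) over two samples: the 3-4-5 triangle
    X = np.array([[0.0, 3.0], [0.0, 4.0]])
    D = euclidean_distance(X).D
    assert D[0, 1] == pytest.approx(5.0)
    # identical columns at distance zero
    X2 = np.column_stack([X[:, 0], X[:, 0]])
    assert euclidean_distance(X2).D[0, 1] == 0.0


def test_correlation_hand_values():
    x = np.array([1.0, 2.0, 3.0])
    D = one_minus_correlation(np.column_stack([x, -x, 2 * x])).D
    assert D[0, 1] == pytest.approx(2.0)  # perfect anticorrelation
    assert D[0, 2] == pytest.approx(0.0)  # exact linear relation
    assert D[0, 0] == 0.0


def test_correlation_zero_variance_fallback():
    X = np.column_stack([np.ones(4), np.arange(4.0)])
    with pytest.warns(RuntimeWarning):
        D = one_minus_correlation(X).D
    assert D[0, 1] == 1.0


def test_geodesic_line_path():
    # three collinear features at gaps 1, 1; k=1 connects only adjacent
    X = np.array([[0.0, 1.0, 2.0]])
    D = geodesic_distance(X, k=1).D
    assert D[0, 2] == pytest.approx(2.0)  # path through the middle feature


def test_geodesic_full_graph_equals_euclidean(rng):
    X = rng.normal(size=(5, 8))
    gd = geodesic_distance(X, k=7).D
    ed = euclidean_distance(X).D
    assert np.allclose(gd, ed)


def test_geodesic_dominates_euclidean(rng):
    for _ in range(5):
        X = rng.normal(size=(6, 8))
        gd = geodesic_distance(X, k=2).D
        ed = euclidean_distance(X).D
        assert (gd >= ed - 1e-9).all()


def test_geodesic_k_out_of_range():
    X = np.random.default_rng(0).random((4, 3))
    with pytest.raises(ValueError):
        geodesic_distance(X, k=3)


def test_js_hand_values():
    # identical PMFs -> 0; disjoint supports -> 1
    X = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    D = jensen_shannon_distance(X).D
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert D[0, 2] == pytest.approx(1.0)


def test_js_direct_summation():
    # (0.5, 0.5) vs (0.9, 0.1): 1/2 KL(X||M) + 1/2 KL(Y||M), M = (0.7, 0.3)
    X = np.array([[0.5, 0.9], [0.5, 0.1]])
    expected = 0.5 * (
        0.5 * np.log2(0.5 / 0.7) + 0.5 * np.log2(0.5 / 0.3)
    ) + 0.5 * (0.9 * np.log2(0.9 / 0.7) + 0.1 * np.log2(0.1 / 0.3))
    assert jensen_shannon_distance(X).D[0, 1] == pytest.approx(expected, abs=1e-12)


def test_js_softmax_branch_on_negative_data(rng):
    X = rng.normal(size=(5, 4))  # contains negatives -> softmax PMFs
    P = feature_pmf(X)
    assert np.allclose(P.sum(axis=0), 1.0)
    assert (P > 0).all()
    D = jensen_shannon_distance(X).D
    assert (D <= 1.0 + 1e-9).all()


def test_js_all_zero_column_uniform_fallback():
    X = np.array([[0.0, 1.0], [0.0, 3.0]])
    with pytest.warns(RuntimeWarning):
        P = feature_pmf(X)
    assert np.allclose(P[:, 0], 0.5)


def test_wasserstein_hand_values(rng):
    # sorted pairs (0,1) vs (2,5): sqrt((4 + 16)/2) = sqrt(10)
    X = np.array([[0.0, 2.0], [1.0, 5.0]])
    assert wasserstein_distance(X).D[0, 1] == pytest.approx(np.sqrt(10.0))
    # a permutation of the same values is at distance zero
    col = rng.normal(size=7)
    X2 = np.column_stack([col, rng.permutation(col)])
    assert wasserstein_distance(X2).D[0, 1] == pytest.approx(0.0, abs=1e-12)
    # constant shift c yields exactly |c|
    X3 = np.column_stack([col, col + 3.25])
    assert wasserstein_distance(X3).D[0, 1] == pytest.approx(3.25)


def test_gaussian_w2_closed_form_values():
    assert gaussian_w2_closed_form(0, 0, 1, 1, 1.0) == pytest.approx(0.0)
    assert gaussian_w2_closed_form(0, 1, 1, 1, 1.0) == pytest.approx(1.0)
    assert gaussian_w2_closed_form(0, 0, 1, 2, 0.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        gaussian_w2_closed_form(0, 0, 1, 1, 1.5)


def test_wasserstein_matches_gaussian_closed_form_limit(rng):
    # N(0,1) vs N(1,1) at n=5000: quantile WD ~ sqrt(W2^2 at rho=1) = 1
    X = np.column_stack([rng.normal(0, 1, 5000), rng.normal(1, 1, 5000)])
    wd = wasserstein_distance(X).D[0, 1]
    assert wd == pytest.approx(np.sqrt(gaussian_w2_closed_form(0, 1, 1, 1, 1.0)), abs=0.05)


def test_tropical_hand_values():
    X = np.array([[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]])
    # differences (-2, 1, 1): max 1 - min -2 = 3
    assert tropical_distance(X).D[0, 1] == pytest.approx(3.0)
    assert tropical_distance(X).D[0, 0] == 0.0


def test_tropical_shift_invariance(rng):
    X = rng.normal(size=(6, 5))
    X2 = X.copy()
    X2[:, 2] += 17.3
    assert np.allclose(tropical_distance(X).D, tropical_distance(X2).D)


# --------------------------------------------------- oracle + invariants

@pytest.mark.parametrize("metric", METRICS)
def test_matches_double_loop_oracle(metric, rng):
    """Vectorized metrics equal the naive scalar reimplementation to 1e-9."""
    for _ in range(3):
        X = rng.random((5, 6)) + 0.05
        D = compute_distance(X, metric, k=2).D
        assert np.abs(D - naive_metric(X, metric, k=2)).max() < 1e-9


@pytest.mark.parametrize("metric", METRICS)
def test_distance_matrix_invariants(metric, rng):
    X = rng.random((7, 9)) + 0.05
    dm = compute_distance(X, metric, k=3)
    D = dm.D
    assert D.shape == (9, 9)
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
    assert (D >= 0).all() and np.isfinite(D).all()
    if metric == "RD":
        assert D.max() <= 2.0 + 1e-9
    if metric == "JD":
        assert D.max() <= 1.0 + 1e-9


@pytest.mark.parametrize("metric", METRICS)
def test_sample_order_invariance(metric, rng):
    X = rng.random((8, 5)) + 0.05
    perm = rng.permutation(8)
    D1 = compute_distance(X, metric, k=2).D
    D2 = compute_distance(X[perm], metric, k=2).D
    assert np.allclose(D1, D2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_metric_properties_random_tables(seed):
    """Symmetry/range invariants hold across random instances (all metrics)."""
    X = np.random.default_rng(seed).random((4, 5)) + 0.01
    for metric in METRICS:
        D = compute_distance(X, metric, k=2).D
        assert np.allclose(D, D.T) and (D >= 0).all()


def test_distance_matrix_save_load(tmp_path, rng):
    from igtdx.distances import DistanceMatrix

    dm = euclidean_distance(rng.random((5, 4)))
    dm.save(tmp_path / "d.npz")
    back = DistanceMatrix.load(tmp_path / "d.npz")
    assert np.allclose(back.D, dm.D) and back.metric_name == "ED"
    dm.save(tmp_path / "d.csv")
    assert np.abs(DistanceMatrix.load(tmp_path / "d.csv").D - dm.D).max() < 1e-12
    with pytest.raises(ValueError):
        dm.save(tmp_path / "d.xyz")
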