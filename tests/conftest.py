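import numpy as np
import pytest

from igtdx.io import TabularDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    """6 features x 5 samples of positive values (valid for every metric)."""
    X = rng.random((5, 6)) + 0.1
    y = np.array([0, 1, 0, 1, 0])
    return TabularDataset(
        X=X, y=y,
        feature_names=[f"f{j}" for j in range(6)],
        sample_ids=[f"s{i}" for i in range(5)],
    )


def naive_metric(X: np.ndarray, metric: str, k: int = 2) -> np.ndarray:
    """Scalar double-loop reimplementation of every metric (test oracle).

    Deliberately independent of the vectorized implementations: plain
    Python loops over feature pairs and samples.
    """
    import math
    from itertools import combinations

    n, p = X.shape
    D = np.zeros((p, p))

    if metric == "ED":
        for i in range(p):
            for j in range(p):
                D[i, j] = math.sqrt(sum((X[s, i] - X[s, j]) ** 2 for s in range(n)))
    elif metric == "RD":
        for i in range(p):
            for j in range(p):
                xi, xj = X[:, i], X[:, j]
                num = sum((xi[s] - xi.mean()) * (xj[s] - xj.mean()) for s in range(n))
                den = math.sqrt(sum((v - xi.mean()) ** 2 for v in xi)) * math.sqrt(
                    sum((v - xj.mean()) ** 2 for v in xj)
                )
                D[i, j] = 0.0 if i == j else 1.0 - (num / den if den else 0.0)
    elif metric == "GD":
        E = naive_metric(X, "ED")
        INF = float("inf")
        adj = np.full((p, p), INF)
        for i in range(p):
            nbrs = sorted(range(p), key=lambda j: (E[i, j], j))
            nbrs = [j for j in nbrs if j != i][:k]
            for j in nbrs:
                adj[i, j] = adj[j, i] = E[i, j]
        # single-linkage bridging of disconnected components
        def comps():
            seen, groups = set(), []
            for s in range(p):
                if s in seen:
                    continue
                stack, grp = [s], set()
                while stack:
                    u = stack.pop()
                    if u in grp:
                        continue
                    grp.add(u)
                    stack.extend(v for v in range(p) if adj[u, v] < INF)
                seen |= grp
                groups.append(grp)
            return groups

        groups = comps()
        while len(groups) > 1:
            best = (INF, None)
            for ga, gb in combinations(groups, 2):
                for u in ga:
                    for v in gb:
                        if E[u, v] < best[0]:
                            best = (E[u, v], (u, v))
            u, v = best[1]
            adj[u, v] = adj[v, u] = E[u, v]
            groups = comps()
        # Floyd-Warshall
        Dg = adj.copy()
        np.fill_diagonal(Dg, 0.0)
        for m in range(p):
            for i in range(p):
                for j in range(p):
                    Dg[i, j] = min(Dg[i, j], Dg[i, m] + Dg[m, j])
        D = Dg
    elif metric == "JD":
        if (X < 0).any():
            P = np.empty_like(X)
            for j in range(p):
                e = np.array([math.exp(v - max(X[:, j])) for v in X[:, j]])
                P[:, j] = e / e.sum()
        else:
            P = X / X.sum(axis=0)
        for i in range(p):
            for j in range(p):
                m = (P[:, i] + P[:, j]) / 2
                kl_i = sum(
                    P[s, i] * math.log2(P[s, i] / m[s]) for s in range(n) if P[s, i] > 0
                )
                kl_j = sum(
                    P[s, j] * math.log2(P[s, j] / m[s]) for s in range(n) if P[s, j] > 0
                )
                D[i, j] = 0.5 * kl_i + 0.5 * kl_j
    elif metric == "WD":
        S = np.sort(X, axis=0)
        for i in range(p):
            for j in range(p):
                D[i, j] = math.sqrt(sum((S[s, i] - S[s, j]) ** 2 for s in range(n)) / n)
    elif metric == "TD":
        for i in range(p):
            for j in range(p):
                diffs = [X[s, i] - X[s, j] for s in range(n)]
                D[i, j] = max(diffs) - min(diffs)
    else:
        raise ValueError(metric)
    return D
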