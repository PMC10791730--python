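import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_weighted_graph(rng, n, density=0.3, distinct=True):
    """Random symmetric weighted graph for oracle comparisons."""
    w = np.zeros((n, n))
    rows, cols = np.triu_indices(n, 1)
    mask = rng.random(rows.size) < density
    vals = rng.random(int(mask.sum())) * 0.9 + 0.05
    if distinct:
        vals = np.unique(vals)
        while vals.size < mask.sum():
            vals = np.unique(np.concatenate([vals, rng.random(int(mask.sum()) - vals.size)]))
    w[rows[mask], cols[mask]] = vals[: int(mask.sum())]
    w += w.T
    return w


def floyd_warshall_oracle(weights):
    """Independent all-pairs shortest paths: plain Floyd-Warshall over 1/w."""
    n = weights.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    mask = weights > 0
    D[mask] = 1.0 / weights[mask]
    for k in range(n):
        D = np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :])
    return D


def clustering_oracle(scaled):
    """Direct triple enumeration of the geometric-mean triangle clustering."""
    n = scaled.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(scaled[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, l = nbrs[a], nbrs[b]
                s += (scaled[i, j] * scaled[j, l] * scaled[l, i]) ** (1 / 3)
        c[i] = 2.0 * s / (k * (k - 1))
    return c


def global_efficiency_oracle(weights):
    D = floyd_warshall_oracle(weights)
    n = D.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(D[off]) & (D[off] > 0), 1.0 / D[off], 0.0)
    return inv.mean()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def triangle_118():
    """3-node triangle with weights {1, 1, 8} (scaled: {0.3, 0.3, 2.4})."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    w[0, 2] = w[2, 0] = 8.0
    return w


@pytest.fixture
def path3():
    """3-node path with unit weights."""
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)


@pytest.fixture
def ws_weighted(rng):
    """One default-condition synthetic subject (N=90 small-world, log-normal weights)."""
    from csvdnet import synthgen

    adj = synthgen.generate_base_topology(90, 10, 0.1, rng)
    return synthgen.assign_weights(adj, -4.0, 0.7, rng)
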