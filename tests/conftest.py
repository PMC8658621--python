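import numpy as np
import pytest

from ustiff.phantom import MassSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A modest phantom with one mass of each major type, shared read-only."""
    center = 96 * 0.75 / 2.0
    z = 4.5 * 2.5
    masses = (
        MassSpec("cancer", (center + 18, center, z), 12.0),
        MassSpec("fibroadenoma", (center - 9, center + 15.6, z), 12.0),
        MassSpec("cyst", (center - 9, center - 15.6, z), 12.0),
    )
    spec = PhantomSpec(grid_shape=(96, 96, 8), breast_radius=33.0, seed=7, masses=masses)
    ss, att, truth, mask = generate_phantom(spec)
    return {"spec": spec, "ss": ss, "att": att, "truth": truth, "mask": mask}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def kmeans_sse(values, labels, k):
    """Within-cluster sum of squares for scalar values."""
    values = np.asarray(values, float)
    total = 0.0
    for c in range(k):
        v = values[labels == c]
        if v.size:
            total += float(((v - v.mean()) ** 2).sum())
    return total


def dp_optimal_sse(values, k):
    """Exact optimal k-partition SSE of scalar values by dynamic programming
    over contiguous segments of the sorted sequence (optimal 1-D clusters
    are contiguous)."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    pre = np.concatenate([[0.0], np.cumsum(v)])
    pre2 = np.concatenate([[0.0], np.cumsum(v**2)])

    def seg(i, j):  # SSE of v[i:j]
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        return s2 - s * s / (j - i)

    inf = float("inf")
    dp = [[inf] * (n + 1) for _ in range(k + 1)]
    dp[0][0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            dp[kk][j] = min(dp[kk - 1][i] + seg(i, j) for i in range(kk - 1, j))
    return dp[k][n]
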