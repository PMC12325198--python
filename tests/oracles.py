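"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts by the O(N^3) triple loop."""
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for j in range(n):
        acc = 0.0
        for k in range(n):
            if k != j and np.isfinite(d[j, k]):
                acc += 1.0 / d[j, k]
        out[j] = acc / (n - 1)
    return out


def brute_global_efficiency(adj: np.ndarray) -> float:
    return float(brute_nodal_efficiency(adj).mean())


def brute_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        m = nbrs.size
        if m < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub)
        acc = 0.0
        for j in range(m):
            for k in range(m):
                if j != k and np.isfinite(d[j, k]):
                    acc += 1.0 / d[j, k]
        out[i] = acc / (m * (m - 1))
    return out


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T


def brute_rm_anova_2way(cells: np.ndarray):
    """Classical sums-of-squares partition of a two-way within-subject design.

    Returns {effect: (F, partial eta squared)} computed from explicit
    marginal means, independent of the contrast-score implementation.
    """
    n, a, b = cells.shape
    grand = cells.mean()
    subj = cells.mean(axis=(1, 2))
    A = cells.mean(axis=(0, 2))
    B = cells.mean(axis=(0, 1))
    AB = cells.mean(axis=0)
    sA = cells.mean(axis=2)  # subject x A
    sB = cells.mean(axis=1)  # subject x B

    ss_a = n * b * ((A - grand) ** 2).sum()
    ss_b = n * a * ((B - grand) ** 2).sum()
    ss_ab = n * ((AB[None] - A[:, None] - B[None] + grand) ** 2).sum()
    ss_sa = b * ((sA - subj[:, None] - A[None] + grand) ** 2).sum()
    ss_sb = a * ((sB - subj[:, None] - B[None] + grand) ** 2).sum()
    ss_sab = ((cells - sA[:, :, None] - sB[:, None, :] - AB[None]
               + subj[:, None, None] + A[None, :, None] + B[None, None, :]
               - grand) ** 2).sum()

    out = {}
    for name, ss_eff, ss_err, df1 in (
        ("A", ss_a, ss_sa, a - 1),
        ("B", ss_b, ss_sb, b - 1),
        ("AxB", ss_ab, ss_sab, (a - 1) * (b - 1)),
    ):
        df2 = df1 * (n - 1)
        F = (ss_eff / df1) / (ss_err / df2)
        out[name] = (F, ss_eff / (ss_eff + ss_err))
    return out
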