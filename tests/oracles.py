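"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: double loops, Floyd-Warshall,
closed-form normal equations.  None of it shares code with the package.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from scipy.stats import t as t_dist


def brute_spearman(counts: np.ndarray) -> np.ndarray:
    """Pairwise Spearman r by explicit rank-then-Pearson double loop."""
    n_otus = counts.shape[1]
    out = np.eye(n_otus)
    for i in range(n_otus):
        for j in range(i + 1, n_otus):
            ri = rankdata(counts[:, i])
            rj = rankdata(counts[:, j])
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def brute_bray_curtis(counts: np.ndarray) -> np.ndarray:
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            x, y = counts[i].astype(float), counts[j].astype(float)
            out[i, j] = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
    return out


def brute_panel(g) -> dict:
    """Graph property panel via Floyd-Warshall and triangle counting."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for a, b in g.edges:
        dist[idx[a]][idx[b]] = dist[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [
        dist[i][j] for i in range(n) for j in range(n) if i != j and dist[i][j] < inf
    ]
    clus = []
    for v in nodes:
        nb = list(g.neighbors(v))
        k = len(nb)
        if k < 2:
            clus.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nb, 2) if g.has_edge(a, b))
        clus.append(2 * links / (k * (k - 1)))
    m = g.number_of_edges()
    return {
        "average_path_distance": sum(finite) / len(finite) if finite else float("nan"),
        "diameter": max(finite) if finite else float("nan"),
        "connectedness": len(finite) / (n * (n - 1)) if n > 1 else 1.0,
        "average_clustering_coefficient": float(np.mean(clus)),
        "density": 2 * m / (n * (n - 1)) if n > 1 else float("nan"),
        "average_degree": 2 * m / n,
        "edges_per_node": m / n,
    }


def brute_ols(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple linear regression from the normal equations."""
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1 - np.sum(resid**2) / sst
    s2 = np.sum(resid**2) / (len(x) - 2)
    t = slope / np.sqrt(s2 / sxx)
    p = 2 * t_dist.sf(abs(t), len(x) - 2)
    return {"slope": slope, "intercept": intercept, "r2": r2, "p": p}
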