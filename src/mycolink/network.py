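"""OTU co-occurrence networks, the property panel, and random-graph nulls.

Edges are robust Spearman rank correlations between OTU abundance
profiles across the samples of one inoculum group: a pair is connected
when |r| > 0.6 and the Benjamini-Hochberg FDR-adjusted p-value is below
0.05 (both strict).  Only OTUs present in at least half of the group's
samples enter the correlation screen.

The null model is the Erdős-Rényi G(n, m) ensemble — uniform random
simple graphs with exactly the observed node and edge counts — against
which each topological metric is compared by a one-sample t-test.

Conventions for disconnected graphs: average path distance and diameter
are computed over reachable pairs only, and connectedness is the
fraction of ordered node pairs joined by some path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import OtuTable

__all__ = [
    "CorrelationNetwork",
    "NetworkProperties",
    "NullDistribution",
    "prevalence_filter",
    "infer_edges",
    "build_networks_by_group",
    "network_properties",
    "er_null_ensemble",
    "compare_to_null",
    "PANEL_METRICS",
    "NULL_METRICS",
]

PANEL_METRICS = [
    "node",
    "edge",
    "edges_per_node",
    "average_degree",
    "average_clustering_coefficient",
    "average_path_distance",
    "density",
    "diameter",
    "connectedness",
    "modularity",
    "module_number",
    "proportion_positive",
]

# sign information does not exist for unsigned random graphs
NULL_METRICS = [m for m in PANEL_METRICS if m != "proportion_positive"]


@dataclass
class NetworkProperties:
    """The topological property panel of one network."""

    node: int
    edge: int
    edges_per_node: float
    average_degree: float
    average_clustering_coefficient: float
    average_path_distance: float
    density: float
    diameter: float
    connectedness: float
    modularity: float
    module_number: float
    proportion_positive: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in PANEL_METRICS}


@dataclass
class CorrelationNetwork:
    """Signed undirected co-occurrence graph over OTU nodes."""

    graph: nx.Graph
    inoculum: str | None = None
    r_threshold: float = 0.6
    q_threshold: float = 0.05

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "otu_a": a,
                "otu_b": b,
                "r": d["r"],
                "q": d["q"],
                "sign": d["sign"],
            }
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "r", "q", "sign"])


def _spearman_matrix(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman r (average ranks for ties) and two-sided p via the
    t approximation.  Constant columns give NaN rather than poisoning the
    whole matrix."""
    n = arr.shape[0]
    ranks = stats.rankdata(arr, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rmat = np.corrcoef(ranks, rowvar=False)
        rmat = np.atleast_2d(rmat)
        r = np.clip(rmat, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pmat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pmat[np.abs(r) >= 1.0] = 0.0
    pmat[~np.isfinite(r)] = np.nan
    return rmat, pmat


def prevalence_filter(table: OtuTable, min_fraction: float = 0.5) -> OtuTable:
    """Keep OTUs present (count > 0) in at least ``min_fraction`` of samples.

    The retention rule is strict on the removal side: an OTU occurring in
    exactly half of the samples is kept.
    """
    n = len(table.sample_ids)
    if n == 0:
        raise ValueError("empty table")
    threshold = int(np.ceil(min_fraction * n))
    presence = (table.counts > 0).sum(axis=0)
    keep = [o for o in table.otu_ids if presence[o] >= threshold]
    return table.subset_otus(keep)


def infer_edges(
    table: OtuTable,
    r_threshold: float = 0.6,
    q_threshold: float = 0.05,
    inoculum: str | None = None,
) -> CorrelationNetwork:
    """Spearman correlation screen over all unordered OTU pairs.

    p-values use the t approximation; BH adjustment is applied jointly
    across every tested pair of this table.  OTUs with constant abundance
    yield no edges.
    """
    counts = table.counts
    n_samples, n_otus = counts.shape
    if n_samples < 4:
        raise ValueError("need >= 4 samples for a meaningful correlation screen")
    g = nx.Graph()
    tax = table.taxonomy
    for o in table.otu_ids:
        genus = tax.loc[o, "genus"] if tax is not None and o in tax.index else None
        g.add_node(o, genus=genus)
    if n_otus >= 2:
        arr = counts.to_numpy(dtype=float)
        rmat, pmat = _spearman_matrix(arr)
        pairs, rvals, pvals = [], [], []
        for i, j in combinations(range(n_otus), 2):
            if np.isfinite(rmat[i, j]) and np.isfinite(pmat[i, j]):
                pairs.append((i, j))
                rvals.append(rmat[i, j])
                pvals.append(pmat[i, j])
        if pairs:
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            ids = table.otu_ids
            for (i, j), r, q in zip(pairs, rvals, qvals):
                if abs(r) > r_threshold and q < q_threshold:
                    g.add_edge(
                        ids[i], ids[j], r=float(r), q=float(q),
                        sign="+" if r > 0 else "-",
                    )
    return CorrelationNetwork(g, inoculum, r_threshold, q_threshold)


def build_networks_by_group(
    table: OtuTable,
    group_col: str = "inoculum",
    min_fraction: float = 0.5,
    r_threshold: float = 0.6,
    q_threshold: float = 0.05,
) -> dict[str, CorrelationNetwork]:
    """One co-occurrence network per level of ``group_col`` (e.g. inoculum)."""
    nets = {}
    for level in sorted(table.sample_meta[group_col].unique()):
        ids = table.sample_meta.index[table.sample_meta[group_col] == level]
        sub = table.subset_samples(list(ids))
        sub = prevalence_filter(sub, min_fraction)
        nets[level] = infer_edges(sub, r_threshold, q_threshold, inoculum=level)
    return nets


def _path_stats(g: nx.Graph) -> tuple[float, float, float]:
    """(average path distance, diameter, connectedness) over reachable pairs."""
    n = g.number_of_nodes()
    total_dist = 0
    reachable = 0
    diameter = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            for d in lengths.values():
                if d > 0:
                    total_dist += d
                    reachable += 1
                    if d > diameter:
                        diameter = d
    avg = total_dist / reachable if reachable else float("nan")
    connectedness = reachable / (n * (n - 1)) if n > 1 else 1.0
    return avg, float(diameter) if reachable else float("nan"), connectedness


def network_properties(net, modularity_seed=None) -> NetworkProperties:
    """Compute the 12-metric property panel of a simple undirected graph.

    Local clustering of degree<2 nodes counts as 0; modularity and module
    number come from greedy modularity maximisation (Clauset-Newman-Moore)
    on the unweighted graph.
    """
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    avg_path, diameter, connectedness = _path_stats(g)
    clustering = float(np.mean(list(nx.clustering(g).values())))
    if m > 0:
        communities = nx.community.greedy_modularity_communities(g)
        modularity = float(nx.community.modularity(g, communities))
        module_number = float(len(communities))
    else:
        modularity = float("nan")
        module_number = float(nx.number_connected_components(g))
    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    known = [s for s in signs if s in ("+", "-")]
    prop_pos = (
        sum(s == "+" for s in known) / len(known) if known else float("nan")
    )
    return NetworkProperties(
        node=n,
        edge=m,
        edges_per_node=m / n,
        average_degree=2 * m / n,
        average_clustering_coefficient=clustering,
        average_path_distance=avg_path,
        density=2 * m / (n * (n - 1)) if n > 1 else float("nan"),
        diameter=diameter,
        connectedness=connectedness,
        modularity=modularity,
        module_number=module_number,
        proportion_positive=prop_pos,
    )


@dataclass
class NullDistribution:
    """Per-metric vectors over an ensemble of G(n, m) random graphs."""

    n_nodes: int
    n_edges: int
    metrics: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return len(next(iter(self.metrics.values()))) if self.metrics else 0

    def means(self) -> pd.Series:
        return pd.Series({k: float(np.mean(v)) for k, v in self.metrics.items()})


def er_null_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 1000,
    seed=None,
    metrics: list[str] | None = None,
) -> NullDistribution:
    """Property panels of ``reps`` uniform random simple graphs G(n, m).

    ``metrics`` restricts the computed panel (all sign-free metrics by
    default); node and edge counts are fixed by construction.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    wanted = list(metrics) if metrics is not None else list(NULL_METRICS)
    unknown = set(wanted) - set(NULL_METRICS)
    if unknown:
        raise ValueError(f"unknown null metrics: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {k: [] for k in wanted}
    needs_panel = bool(
        set(wanted)
        - {"node", "edge", "edges_per_node", "average_degree", "density"}
    )
    for _ in range(reps):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=rng)
        if needs_panel:
            panel = _partial_panel(g, wanted)
        else:
            panel = {}
        for k in wanted:
            if k in panel:
                out[k].append(panel[k])
            else:
                out[k].append(_closed_form_metric(k, n_nodes, n_edges))
    return NullDistribution(
        n_nodes, n_edges, {k: np.asarray(v, dtype=float) for k, v in out.items()}
    )


def _closed_form_metric(name: str, n: int, m: int) -> float:
    return {
        "node": float(n),
        "edge": float(m),
        "edges_per_node": m / n,
        "average_degree": 2 * m / n,
        "density": 2 * m / (n * (n - 1)) if n > 1 else float("nan"),
    }[name]


def _partial_panel(g: nx.Graph, wanted: list[str]) -> dict[str, float]:
    panel: dict[str, float] = {}
    if {"average_path_distance", "diameter", "connectedness"} & set(wanted):
        avg, diam, conn = _path_stats(g)
        panel.update(
            average_path_distance=avg, diameter=diam, connectedness=conn
        )
    if "average_clustering_coefficient" in wanted:
        panel["average_clustering_coefficient"] = float(
            np.mean(list(nx.clustering(g).values()))
        )
    if {"modularity", "module_number"} & set(wanted):
        if g.number_of_edges() > 0:
            communities = nx.community.greedy_modularity_communities(g)
            panel["modularity"] = float(nx.community.modularity(g, communities))
            panel["module_number"] = float(len(communities))
        else:
            panel["modularity"] = float("nan")
            panel["module_number"] = float(nx.number_connected_components(g))
    return panel


def compare_to_null(observed: NetworkProperties, null: NullDistribution) -> pd.DataFrame:
    """One-sample t-test of each null metric vector against the observed value.

    Metrics whose null vector has zero variance (node and edge counts by
    construction) are flagged degenerate and not tested.
    """
    rows = []
    obs = observed.as_dict()
    for name, vec in null.metrics.items():
        vec = np.asarray(vec, dtype=float)
        finite = vec[np.isfinite(vec)]
        value = obs[name]
        row = {
            "metric": name,
            "observed": value,
            "null_mean": float(finite.mean()) if finite.size else float("nan"),
        }
        if finite.size < 2 or np.ptp(finite) == 0:
            row.update(t=np.nan, p=np.nan, direction=0.0, degenerate=True)
        else:
            res = stats.ttest_1samp(finite, value)
            row.update(
                t=float(res.statistic),
                p=float(res.pvalue),
                direction=float(np.sign(value - finite.mean())),
                degenerate=False,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
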