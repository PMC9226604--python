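"""Per-sample sub-networks and regressions of plant responses on them.

Each sequenced root sample inherits an induced subgraph of its inoculum's
co-occurrence network: the nodes are the network OTUs present (count > 0)
in that sample and the edges are inherited from the parent, never
re-inferred.  The node count, edge count, and average degree of these
sub-networks measure per-sample network complexity, which is then
regressed (OLS) against the sample's plant responses (MGR, PSF).

The same regression engine screens per-sample alpha/beta diversity and
the relative abundances of the most abundant OTUs against the responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import OtuTable
from .network import CorrelationNetwork

__all__ = [
    "RegressionResult",
    "sample_subnetwork",
    "subnetwork_property_table",
    "link_regression",
    "abundance_response_screen",
    "diversity_response_screen",
]


@dataclass
class RegressionResult:
    """Simple OLS fit y = intercept + slope * x."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r2: float
    p: float
    n: int

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "response": self.response,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "p": self.p,
            "n": self.n,
        }


def sample_subnetwork(parent: CorrelationNetwork, sample_counts) -> CorrelationNetwork:
    """Induced subgraph on the parent OTUs present in one sample.

    ``sample_counts`` maps OTU id -> count (a pandas Series row of the
    count table).  A sample containing no parent OTU yields an empty
    graph (flagged by its zero node count).
    """
    counts = pd.Series(sample_counts)
    present = {o for o, c in counts.items() if c > 0}
    nodes = [n for n in parent.graph.nodes if n in present]
    sub = parent.graph.subgraph(nodes).copy()
    return CorrelationNetwork(
        sub, parent.inoculum, parent.r_threshold, parent.q_threshold
    )


def subnetwork_property_table(
    networks: dict[str, CorrelationNetwork],
    root_table: OtuTable,
    responses: pd.DataFrame,
) -> pd.DataFrame:
    """One row per retained root sample: sub-network complexity + responses.

    ``responses`` must carry ``pot_id``, ``MGR`` and/or ``PSF``; root
    samples map to pots through the ``pot_id`` column of the sample
    metadata.  Samples of control pots never appear (their responses are
    undefined), and an inoculated sample without a matching pot is an
    error.
    """
    meta = root_table.sample_meta
    if "pot_id" not in meta.columns:
        raise ValueError("root sample metadata needs a pot_id column")
    resp = responses.set_index("pot_id")
    rows = []
    unmatched = []
    for sid in root_table.sample_ids:
        inoc = meta.loc[sid, "inoculum"]
        if inoc == "control" or inoc not in networks:
            continue
        pot = meta.loc[sid, "pot_id"]
        if pot not in resp.index:
            unmatched.append(sid)
            continue
        sub = sample_subnetwork(networks[inoc], root_table.counts.loc[sid])
        n = sub.graph.number_of_nodes()
        m = sub.graph.number_of_edges()
        row = {
            "sample_id": sid,
            "host": meta.loc[sid, "host"],
            "inoculum": inoc,
            "node": n,
            "edge": m,
            "average_degree": 2 * m / n if n else 0.0,
        }
        for col in ("MGR", "PSF"):
            if col in resp.columns:
                row[col] = float(resp.loc[pot, col])
        rows.append(row)
    if unmatched:
        raise ValueError(f"root samples without a matching pot response: {unmatched}")
    return pd.DataFrame(rows)


def link_regression(
    records: pd.DataFrame, predictor: str, response: str
) -> RegressionResult:
    """OLS of ``response`` on ``predictor`` with a two-sided slope test."""
    data = records[[predictor, response]].dropna()
    x = data[predictor].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 records with finite predictor and response")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        predictor=predictor,
        response=response,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(x),
    )


def abundance_response_screen(
    root_table: OtuTable,
    responses: pd.DataFrame,
    top_k: int = 20,
    responses_to_test: tuple[str, ...] = ("MGR", "PSF"),
) -> pd.DataFrame:
    """Regress the relative abundance of the top-k OTUs against responses.

    OTUs are ranked by total reads; p-values are BH-adjusted across the
    whole screen.  Constant-abundance OTUs are reported with a
    zero-variance flag instead of a fit.
    """
    if top_k > len(root_table.otu_ids):
        raise ValueError("top_k exceeds the number of OTUs")
    meta = root_table.sample_meta
    if "pot_id" not in meta.columns:
        raise ValueError("root sample metadata needs a pot_id column")
    resp = responses.set_index("pot_id")
    totals = root_table.counts.sum(axis=0).sort_values(ascending=False)
    top = totals.index[:top_k]
    rel = root_table.counts.div(root_table.library_sizes, axis=0)

    rows = []
    for otu in top:
        for response in responses_to_test:
            if response not in resp.columns:
                continue
            recs = []
            for sid in root_table.sample_ids:
                pot = meta.loc[sid, "pot_id"]
                if pot in resp.index and np.isfinite(resp.loc[pot, response]):
                    recs.append((rel.loc[sid, otu], resp.loc[pot, response]))
            frame = pd.DataFrame(recs, columns=["abundance", response])
            base = {"otu_id": otu, "predictor": "abundance", "response": response}
            if len(frame) < 3 or np.ptp(frame["abundance"].to_numpy()) == 0:
                rows.append({**base, "slope": np.nan, "r2": np.nan, "p": np.nan,
                             "n": len(frame), "zero_variance": True})
            else:
                fit = link_regression(frame, "abundance", response)
                rows.append({**base, "slope": fit.slope, "r2": fit.r2,
                             "p": fit.p, "n": fit.n, "zero_variance": False})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def diversity_response_screen(
    alpha: pd.DataFrame,
    dist,
    root_table: OtuTable,
    responses: pd.DataFrame,
    group_col: str = "inoculum",
) -> pd.DataFrame:
    """Regress per-sample alpha diversity and mean within-group Bray-Curtis
    distance against MGR and PSF.

    The beta-diversity predictor of a sample is its mean distance to the
    other samples of its group (a per-sample summary of community
    dissimilarity; the choice is a convention, stated here because no
    single standard exists).
    """
    meta = root_table.sample_meta
    resp = responses.set_index("pot_id")
    ddf = dist.to_dataframe()
    rows = []
    for sid in alpha.index:
        if sid not in meta.index or meta.loc[sid, "pot_id"] not in resp.index:
            continue
        pot = meta.loc[sid, "pot_id"]
        group = meta.loc[sid, group_col]
        mates = [
            s for s in alpha.index
            if s != sid and s in meta.index and meta.loc[s, group_col] == group
        ]
        rows.append(
            {
                "sample_id": sid,
                "richness": alpha.loc[sid, "richness"],
                "shannon": alpha.loc[sid, "shannon"],
                "mean_within_group_bc": ddf.loc[sid, mates].mean() if mates else np.nan,
                "MGR": resp.loc[pot, "MGR"] if "MGR" in resp.columns else np.nan,
                "PSF": resp.loc[pot, "PSF"] if "PSF" in resp.columns else np.nan,
            }
        )
    records = pd.DataFrame(rows)
    out = []
    for predictor in ("richness", "shannon", "mean_within_group_bc"):
        for response in ("MGR", "PSF"):
            sub = records[[predictor, response]].dropna()
            if len(sub) >= 3 and np.ptp(sub[predictor].to_numpy()) > 0:
                fit = link_regression(sub, predictor, response)
                out.append(fit.as_dict())
    return pd.DataFrame(out)
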