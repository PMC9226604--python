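"""Rarefaction-based alpha diversity, Bray-Curtis beta diversity, PERMANOVA.

Alpha diversity follows the repeated-rarefaction convention: every sample
is subsampled without replacement (multivariate hypergeometric) to a
common depth many times, and richness and Shannon entropy (natural log)
are averaged over the rarefied tables.

PERMANOVA partitions the Gower-centred distance matrix by sequential
(Type I) terms, in the order the caller lists them; significance comes
from free permutation of sample labels, with the standard
(1 + more-extreme) / (1 + n_perm) permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_tables import OtuTable

__all__ = [
    "DistanceMatrix",
    "rarefy_once",
    "alpha_over_rarefactions",
    "bray_curtis",
    "within_among_test",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    ids: list[str]
    data: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal not zero")
        self.data = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rarefy_once(table: OtuTable, depth: int, seed=None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement."""
    rng = _as_rng(seed)
    depths = table.library_sizes
    shallow = depths[depths < depth].index.tolist()
    if shallow:
        raise ValueError(f"samples shallower than depth {depth}: {shallow}")
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for k in range(counts.shape[0]):
        out[k] = rng.multivariate_hypergeometric(counts[k], depth)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(rarefied, table.sample_meta, table.taxonomy)


def _alpha_of(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    richness = (counts > 0).sum(axis=1).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return richness, -plogp.sum(axis=1)


def alpha_over_rarefactions(
    table: OtuTable, depth: int = 5283, reps: int = 1000, seed=None
) -> pd.DataFrame:
    """Mean richness S and Shannon H' (nats) over repeated rarefactions."""
    rng = _as_rng(seed)
    rich = np.zeros(len(table.sample_ids))
    shan = np.zeros(len(table.sample_ids))
    for _ in range(reps):
        r = rarefy_once(table, depth, rng)
        s, h = _alpha_of(r.counts.to_numpy())
        rich += s
        shan += h
    out = pd.DataFrame(
        {"richness": rich / reps, "shannon": shan / reps}, index=table.sample_ids
    )
    out.attrs["depth"] = depth
    out.attrs["n_rarefactions"] = reps
    return out


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, BC(x, y) = 1 - 2 sum min(x,y) / sum(x+y)."""
    if isinstance(table, OtuTable):
        counts = table.counts
    else:
        counts = pd.DataFrame(table)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    zero = counts.index[arr.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples: {zero}")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix([str(i) for i in counts.index], d, "braycurtis")


def within_among_test(dist: DistanceMatrix, grouping) -> dict:
    """Compare unordered pair distances within vs among groups by t-test."""
    groups = pd.Series(grouping)
    groups = groups.loc[dist.ids]
    within, among = [], []
    for i, j in combinations(range(len(dist.ids)), 2):
        (within if groups.iloc[i] == groups.iloc[j] else among).append(dist.data[i, j])
    if not within or not among:
        raise ValueError("grouping yields an empty within or among class")
    w, a = np.asarray(within), np.asarray(among)
    if np.ptp(np.concatenate([w, a])) == 0:
        return {
            "t": 0.0,
            "df": len(w) + len(a) - 2,
            "p": 1.0,
            "mean_within": float(w.mean()),
            "mean_among": float(a.mean()),
        }
    res = stats.ttest_ind(w, a, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "mean_within": float(w.mean()),
        "mean_among": float(a.mean()),
    }


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design(factors: pd.DataFrame, terms: list[str]) -> list[np.ndarray]:
    """Cumulative hat matrices for intercept + each sequential term."""
    n = len(factors)
    x = np.ones((n, 1))
    hats = []
    for term in ["1"] + terms:
        if term != "1":
            parts = term.split(":")
            d = pd.get_dummies(
                factors[parts].astype(str).agg(":".join, axis=1), drop_first=False
            ).to_numpy(dtype=float)
            x = np.hstack([x, d])
        hats.append(x @ np.linalg.pinv(x))
    return hats


def permanova(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Sequential-terms PERMANOVA on a distance matrix.

    ``terms`` are fitted in order; an entry like ``"host:inoculum"`` adds
    the interaction.  Returns a DataFrame indexed by term (plus
    ``Residual`` and ``Total``) with ``df``, ``SS``, ``R2``, ``pseudo_F``,
    ``p``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    factors = pd.DataFrame(factors).loc[dist.ids]
    if terms is None:
        terms = list(factors.columns)
    for term in terms:
        for col in term.split(":"):
            if factors[col].nunique() < 2:
                raise ValueError(f"factor {col!r} has a single level")
    rng = _as_rng(seed)
    n = len(dist.ids)
    g = _gower_center(dist.data)
    hats = _design(factors, terms)
    ranks = [int(np.round(np.trace(h))) for h in hats]
    df_terms = np.diff(ranks)
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(gmat: np.ndarray):
        fitted = np.array([np.sum(h * gmat) for h in hats])  # trace(H G)
        ss_terms = np.diff(fitted)
        ss_resid = np.trace(gmat) - fitted[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_terms / df_terms) / (ss_resid / df_resid)
        return ss_terms, ss_resid, f

    ss_terms, ss_resid, f_obs = term_stats(g)
    ss_total = float(np.trace(g))
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, _, f_perm = term_stats(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "df": int(df_terms[k]),
                "SS": float(ss_terms[k]),
                "R2": float(ss_terms[k] / ss_total),
                "pseudo_F": float(f_obs[k]),
                "p": float(pvals[k]),
            }
        )
    rows.append(
        {
            "df": df_resid,
            "SS": float(ss_resid),
            "R2": float(ss_resid / ss_total),
            "pseudo_F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"df": n - 1, "SS": ss_total, "R2": 1.0, "pseudo_F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows, index=terms + ["Residual", "Total"])
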