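"""Plant growth responses to inoculation: MGR, PSF, and their tests.

The mycorrhizal growth response of an inoculated pot is the log response
ratio MGR = ln(AM / NM), where AM is the pot's total biomass and NM is
the mean total biomass of that host's uninoculated control pots.
Positive values indicate mutualism, negative values parasitism.

Plant-soil feedback contrasts conspecific with heterospecific inoculum:
at the host level PSF = ln(mean conspecific biomass / mean heterospecific
biomass).  To obtain one value per pot (needed when regressing responses
on per-sample community predictors) each pot's own biomass replaces its
category's mean: a conspecific pot contributes ln(biomass / mean hetero),
a heterospecific pot ln(mean conspecific / biomass).  The mean of the
conspecific contributions converges to the host-level value as noise
vanishes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import validate_traits

__all__ = [
    "compute_mgr",
    "compute_psf",
    "compute_responses",
    "host_level_psf",
    "test_nonzero",
    "two_way_anova",
]


def _control_means(traits: pd.DataFrame) -> pd.Series:
    controls = traits[traits["inoculum"] == "control"]
    missing = sorted(set(traits["host"]) - set(controls["host"]))
    if missing:
        raise ValueError(f"no control pots for hosts: {missing}")
    if (traits["total_biomass"] <= 0).any():
        raise ValueError("non-positive total biomass")
    return controls.groupby("host")["total_biomass"].mean()


def compute_mgr(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-pot MGR = ln(pot biomass / mean control biomass of its host).

    Control pots are excluded from the result (their MGR is undefined).
    """
    traits = validate_traits(traits)
    nm = _control_means(traits)
    out = traits[traits["inoculum"] != "control"].copy()
    out["MGR"] = np.log(out["total_biomass"].to_numpy() / nm.loc[out["host"]].to_numpy())
    return out[["pot_id", "host", "inoculum", "MGR"]].reset_index(drop=True)


def _category_means(traits: pd.DataFrame):
    inoculated = traits[traits["inoculum"] != "control"]
    con = inoculated[inoculated["inoculum"] == inoculated["host"]]
    het = inoculated[inoculated["inoculum"] != inoculated["host"]]
    for name, frame in (("conspecific", con), ("heterospecific", het)):
        missing = sorted(set(inoculated["host"]) - set(frame["host"]))
        if missing:
            raise ValueError(f"no {name} pots for hosts: {missing}")
    return (
        con.groupby("host")["total_biomass"].mean(),
        het.groupby("host")["total_biomass"].mean(),
    )


def compute_psf(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-pot plant-soil feedback attribution (controls excluded)."""
    traits = validate_traits(traits)
    con_mean, het_mean = _category_means(traits)
    out = traits[traits["inoculum"] != "control"].copy()
    biomass = out["total_biomass"].to_numpy()
    is_con = (out["inoculum"] == out["host"]).to_numpy()
    psf = np.where(
        is_con,
        np.log(biomass / het_mean.loc[out["host"]].to_numpy()),
        np.log(con_mean.loc[out["host"]].to_numpy() / biomass),
    )
    out["PSF"] = psf
    return out[["pot_id", "host", "inoculum", "PSF"]].reset_index(drop=True)


def host_level_psf(traits: pd.DataFrame) -> pd.Series:
    """Host-level PSF = ln(mean conspecific / mean heterospecific biomass)."""
    con_mean, het_mean = _category_means(validate_traits(traits))
    return np.log(con_mean / het_mean).rename("PSF")


def compute_responses(traits: pd.DataFrame) -> pd.DataFrame:
    """Joint per-pot response table with MGR and PSF columns."""
    mgr = compute_mgr(traits)
    psf = compute_psf(traits)
    out = mgr.merge(psf, on=["pot_id", "host", "inoculum"], validate="1:1")
    out.attrs["group_means"] = (
        validate_traits(traits)
        .groupby(["host", "inoculum"], observed=True)["total_biomass"]
        .mean()
        .unstack()
    )
    return out


def test_nonzero(values) -> dict:
    """One-sample two-sided t-test of ``values`` against zero.

    Returns ``{"t", "df", "p", "mean", "degenerate"}``; a zero-variance
    sample is flagged degenerate (t undefined) rather than tested.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        return {
            "t": np.nan,
            "df": x.size - 1,
            "p": np.nan,
            "mean": float(x.mean()),
            "degenerate": True,
        }
    res = stats.ttest_1samp(x, 0.0)
    return {
        "t": float(res.statistic),
        "df": x.size - 1,
        "p": float(res.pvalue),
        "mean": float(x.mean()),
        "degenerate": False,
    }


def two_way_anova(
    traits: pd.DataFrame,
    response_field: str,
    factors: tuple[str, str] = ("host", "inoculum"),
) -> pd.DataFrame:
    """Two-way crossed ANOVA with interaction; Type II sums of squares.

    Returns a DataFrame indexed by term (factor names, ``a:b``,
    ``Residual``) with columns ``sum_sq``, ``df``, ``F``, ``p``.  A
    constant response yields F = 0 for every term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    a, b = factors
    for f in factors:
        if traits[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = traits.groupby([a, b], observed=True).size()
    full = pd.MultiIndex.from_product([traits[a].unique(), traits[b].unique()])
    empty = sorted(set(full) - set(cells.index))
    if empty:
        raise ValueError(f"empty design cells: {empty}")

    data = traits[[a, b, response_field]].rename(columns={response_field: "_y"})
    if np.ptp(data["_y"].to_numpy(dtype=float)) == 0:
        terms = [a, b, f"{a}:{b}", "Residual"]
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": [0.0, 0.0, 0.0, np.nan], "p": np.nan},
            index=terms,
        )
    model = smf.ols(f"_y ~ C({a}) * C({b})", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            f"C({a})": a,
            f"C({b})": b,
            f"C({a}):C({b})": f"{a}:{b}",
        },
        columns={"PR(>F)": "p"},
    )
    return table[["sum_sq", "df", "F", "p"]]
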