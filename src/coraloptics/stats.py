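"""Group classification and bleaching statistics.

The analysis isolates light- from temperature-dependent bleaching with a
first-order Taylor expansion of the temporal rate of photochemical
efficiency loss, ``PE_i = d(Fv/Fm)_i/dt``, over temperature, irradiance,
and an additive nuisance term ``X_i`` collecting every ramet-specific
condition not under experimental control::

    PE_i(T, I) = X_i + dT * dPE/dT + dI * dPE/dI

Differencing PE across the light factor at fixed temperature (or across
temperature at fixed light) cancels ``X_i`` exactly::

    dPE(T_j) = PE(T_j, HL) - PE(T_j, CL)      light basis
    dPE(I_j) = PE(HT, I_j) - PE(CT, I_j)      temperature basis

PE is estimated per ramet as the OLS slope of the metric on day over the
stress window and averaged to the species x treatment cell before
differencing (ramets are distinct physical individuals across cells, so
the per-ramet difference can only be realized at cell level).

Group-level temporal rates are estimated by a clustered longitudinal
model ``metric ~ group * day`` over the stress window with colony-level
clustering: a two-stage cluster-summary estimator by default (per-colony
OLS slopes, Welch t between groups), with pooled cluster-robust OLS and
a random-intercept linear mixed model as alternatives; on balanced
designs all three reproduce the within-group pooled OLS slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .datamodel import Group, ObservationTable, OpticalProfile, TreatmentLevel

__all__ = [
    "RateEstimate",
    "DeltaPE",
    "RegressionResult",
    "GroupRateModel",
    "MarginalComparison",
    "BaselineComparison",
    "classify_scattering_group",
    "group_map",
    "pe_slope",
    "ramet_pe_table",
    "cell_pe_table",
    "delta_pe",
    "regress_depe",
    "clustered_rate_model",
    "marginal_day_comparison",
    "baseline_compare",
    "STRESS_WINDOW",
]

#: Default stress window (days after stress onset).
STRESS_WINDOW = (0, 11)


@dataclass(frozen=True)
class RateEstimate:
    """OLS temporal slope of a metric over a day window."""

    slope: float
    se: float
    n: int
    p: float
    window: tuple[int, int]


@dataclass(frozen=True)
class DeltaPE:
    """Light- or temperature-isolated PE difference for one species.

    ``basis='light'``: PE(T_j, HL) - PE(T_j, CL), conditioned on the
    temperature level ``conditioning``; ``basis='temperature'``:
    PE(HT, I_j) - PE(CT, I_j), conditioned on the light level.
    """

    species: str
    basis: str
    conditioning: str  # "CT"/"HT" for light basis, "CL"/"HL" for temperature basis
    value: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupRateModel:
    """Per-group slopes and the group x day interaction test."""

    slopes: dict[str, float]
    slope_se: dict[str, float]
    slope_p: dict[str, float]
    interaction_p: float
    method: str
    cluster: str
    n_clusters: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class MarginalComparison:
    day: int
    difference: float  # mean(high) - mean(low)
    p: float
    n_low: int
    n_high: int
    normalized: bool


@dataclass(frozen=True)
class BaselineComparison:
    difference: float  # mean(high) - mean(low) of ramet baseline means
    t: float
    p: float
    n_low: int
    n_high: int


def classify_scattering_group(
    profiles: Sequence[OpticalProfile],
) -> list[OpticalProfile]:
    """Assign low/high scattering groups by the across-species mean of
    mu'_S,m: below the mean -> low, at or above (ties included) -> high.
    With fewer than 2 species all profiles stay unassigned."""
    if len(profiles) < 2:
        warnings.warn("need >= 2 species to classify scattering groups; left unassigned")
        return [p.with_group(Group.UNASSIGNED) for p in profiles]
    threshold = float(np.mean([p.mu_sm for p in profiles]))
    out = []
    for p in profiles:
        grp = Group.LOW if p.mu_sm < threshold else Group.HIGH
        if p.group is not Group.UNASSIGNED and p.group is not grp:
            raise ValueError(
                f"{p.species}: preset group {p.group.value!r} contradicts "
                f"threshold classification {grp.value!r} (threshold {threshold:.4g})"
            )
        out.append(p.with_group(grp))
    return out


def group_map(profiles: Sequence[OpticalProfile]) -> dict[str, str]:
    """species -> group-name mapping, classifying first if needed."""
    if any(p.group is Group.UNASSIGNED for p in profiles):
        profiles = classify_scattering_group(profiles)
    return {p.species: p.group.value for p in profiles}


def pe_slope(
    series: Sequence[tuple[float, float]] | pd.DataFrame,
    window: tuple[int, int] = STRESS_WINDOW,
) -> RateEstimate:
    """OLS slope of a (day, metric) series within the window, with the
    standard slope t-test."""
    if isinstance(series, pd.DataFrame):
        pairs = list(zip(series.iloc[:, 0], series.iloc[:, 1]))
    else:
        pairs = list(series)
    lo, hi = window
    pts = [(d, v) for d, v in pairs if lo <= d <= hi and not pd.isna(v)]
    if len(pts) < 2:
        raise ValueError(f"need >= 2 points in window [{lo}, {hi}], got {len(pts)}")
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    if np.ptp(x) == 0:
        raise ValueError("all points at the same day; slope undefined")
    res = sps.linregress(x, y)
    n = len(pts)
    # linregress returns nan se/p for a perfect 2-point fit; normalize
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else float("nan")
    return RateEstimate(slope=float(res.slope), se=se, n=n, p=p, window=(lo, hi))


def ramet_pe_table(
    table: ObservationTable,
    metric: str = "fvfm",
    window: tuple[int, int] = STRESS_WINDOW,
) -> pd.DataFrame:
    """Per-ramet OLS slopes: one row per species x colony x ramet x cell."""
    df = table.subset(window=window)
    df = df[df[metric].notna()]
    rows = []
    for (sp, col, ram, temp, light), sub in df.groupby(
        ["species", "colony", "ramet", "temperature", "light"], sort=False
    ):
        if len(sub) < 2:
            continue
        est = pe_slope(list(zip(sub["day"], sub[metric])), window)
        rows.append(
            {
                "species": sp, "colony": col, "ramet": ram,
                "temperature": temp, "light": light,
                "slope": est.slope, "se": est.se, "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def cell_pe_table(
    table: ObservationTable,
    metric: str = "fvfm",
    window: tuple[int, int] = STRESS_WINDOW,
) -> pd.DataFrame:
    """Species x treatment-cell PE: mean over ramet-level slopes."""
    ramets = ramet_pe_table(table, metric, window)
    if ramets.empty:
        raise ValueError("no ramet-level slopes could be computed")
    return (
        ramets.groupby(["species", "temperature", "light"], sort=False)["slope"]
        .mean()
        .reset_index()
        .rename(columns={"slope": "pe"})
    )


def delta_pe(pe_table: pd.DataFrame, basis: str) -> list[DeltaPE]:
    """Difference cell-level PE values per species.

    ``basis='light'``: dPE(T_j) = PE(T_j, HL) - PE(T_j, CL), j in {CT, HT};
    ``basis='temperature'``: dPE(I_j) = PE(HT, I_j) - PE(CT, I_j), j in
    {CL, HL}.  Species missing a required cell are skipped with a warning.
    """
    if basis not in ("light", "temperature"):
        raise ValueError(f"basis must be 'light' or 'temperature', got {basis!r}")
    out: list[DeltaPE] = []
    for sp, sub in pe_table.groupby("species", sort=False):
        cells = {(r["temperature"], r["light"]): r["pe"] for _, r in sub.iterrows()}
        if basis == "light":
            pairs = [("CT", ("CT", "HL"), ("CT", "CL")), ("HT", ("HT", "HL"), ("HT", "CL"))]
        else:
            pairs = [("CL", ("HT", "CL"), ("CT", "CL")), ("HL", ("HT", "HL"), ("CT", "HL"))]
        for cond, hi_cell, lo_cell in pairs:
            if hi_cell not in cells or lo_cell not in cells:
                warnings.warn(f"{sp}: missing cell for {basis} basis at {cond}; skipped")
                continue
            out.append(
                DeltaPE(species=sp, basis=basis, conditioning=cond,
                        value=float(cells[hi_cell] - cells[lo_cell]))
            )
    return out


def regress_depe(
    depe: Sequence[DeltaPE] | Mapping[str, float] | pd.DataFrame,
    profiles: Sequence[OpticalProfile],
) -> RegressionResult:
    """OLS of species-level dPE on mu'_S,m."""
    if isinstance(depe, pd.DataFrame):
        values = dict(zip(depe["species"], depe["value"]))
    elif isinstance(depe, Mapping):
        values = dict(depe)
    else:
        values = {d.species: d.value for d in depe}
    mu = {p.species: p.mu_sm for p in profiles}
    common = [s for s in values if s in mu]
    if len(common) < 3:
        raise ValueError(f"need >= 3 species with both dPE and mu_sm, got {len(common)}")
    x = np.array([mu[s] for s in common])
    y = np.array([values[s] for s in common])
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p=float(res.pvalue), n=len(common),
    )


def _prep_model_frame(
    table: ObservationTable,
    metric: str,
    groups: Mapping[str, str],
    treatment: str | TreatmentLevel,
    window: tuple[int, int],
) -> pd.DataFrame:
    df = table.subset(treatment=treatment, window=window)
    df = df[df[metric].notna()].copy()
    df["group"] = df["species"].map(dict(groups))
    df = df[df["group"].isin(["low", "high"])]
    if df.empty:
        raise ValueError("no observations for the requested metric/treatment/window")
    df["group"] = pd.Categorical(df["group"], categories=["low", "high"])
    df["cluster_id"] = df["species"] + "/" + df["colony"]
    df = df.rename(columns={metric: "y"})
    return df


def clustered_rate_model(
    table: ObservationTable,
    metric: str,
    groups: Mapping[str, str],
    treatment: str | TreatmentLevel = "HT-HL",
    window: tuple[int, int] = STRESS_WINDOW,
    method: str = "colony_slopes",
    cluster: str = "colony",
) -> GroupRateModel:
    """Clustered longitudinal model ``metric ~ group * day`` over the
    stress window, with colony-level clustering.

    Methods (all agree on group-slope point estimates for balanced
    designs, where each equals the within-group pooled OLS slope):

    * ``'colony_slopes'`` (default) — two-stage cluster-summary
      estimator: an OLS slope per colony, group slopes as colony-slope
      means, interaction p from a Welch t-test between the group
      colony-slope sets.  Exactly calibrated for balanced clusters.
    * ``'cluster_robust'`` — pooled OLS with cluster-robust covariance
      and a t reference on n_clusters - 1 degrees of freedom.
    * ``'mixedlm'`` — random-intercept-per-cluster linear mixed model.

    ``interaction_p`` tests the group x day term in every case.
    """
    df = _prep_model_frame(table, metric, groups, treatment, window)
    if cluster == "colony":
        cl = df["cluster_id"]
    elif cluster == "species":
        cl = df["species"]
    else:
        raise ValueError(f"cluster must be 'colony' or 'species', got {cluster!r}")
    n_clusters = cl.nunique()
    flags: tuple[str, ...] = ()
    per_group_clusters = df.groupby("group", observed=True)["cluster_id"].nunique()
    if (per_group_clusters < 2).any():
        flags += ("single-cluster-group: inference unreliable",)

    if method == "colony_slopes":
        df = df.assign(_cl=cl)
        slopes: dict[str, list[float]] = {"low": [], "high": []}
        for (_, grp), sub in df.groupby(["_cl", "group"], observed=True):
            if len(sub) < 2 or sub["day"].nunique() < 2:
                continue
            x = sub["day"].to_numpy(float)
            y = sub["y"].to_numpy(float)
            xc = x - x.mean()
            slopes[str(grp)].append(float(xc @ (y - y.mean()) / (xc @ xc)))
        if not slopes["low"] or not slopes["high"]:
            raise ValueError("both groups need at least one cluster with >= 2 days")
        out_slopes, out_se, out_p = {}, {}, {}
        for g, vals in slopes.items():
            arr = np.asarray(vals)
            out_slopes[g] = float(arr.mean())
            if len(arr) > 1:
                out_se[g] = float(arr.std(ddof=1) / np.sqrt(len(arr)))
                t_stat = out_slopes[g] / out_se[g] if out_se[g] > 0 else np.inf
                out_p[g] = float(2 * sps.t.sf(abs(t_stat), len(arr) - 1))
            else:
                out_se[g], out_p[g] = float("nan"), float("nan")
        inter = sps.ttest_ind(slopes["high"], slopes["low"], equal_var=False)
        return GroupRateModel(
            slopes=out_slopes, slope_se=out_se, slope_p=out_p,
            interaction_p=float(inter.pvalue), method=method, cluster=cluster,
            n_clusters=int(n_clusters), flags=flags,
        )

    formula = "y ~ C(group) * day"
    if method == "cluster_robust":
        fit = smf.ols(formula, data=df).fit(
            cov_type="cluster", cov_kwds={"groups": cl}, use_t=True
        )
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    elif method == "mixedlm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data=df, groups=cl).fit(reml=True)
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    else:
        raise ValueError(f"method must be 'cluster_robust' or 'mixedlm', got {method!r}")

    b_day = float(params["day"])
    inter_name = [k for k in params.index if "day" in k and "group" in k][0]
    b_int = float(params[inter_name])
    se_low = float(bse["day"])
    # SE of high-group slope (sum of two coefficients) via the covariance
    cov = fit.cov_params()
    var_high = cov.loc["day", "day"] + cov.loc[inter_name, inter_name] + 2 * cov.loc["day", inter_name]
    se_high = float(np.sqrt(max(var_high, 0.0)))
    if method == "cluster_robust":
        dof = n_clusters - 1
        p_high = 2 * sps.t.sf(abs((b_day + b_int) / se_high), dof) if se_high > 0 else float("nan")
    else:
        p_high = 2 * sps.norm.sf(abs((b_day + b_int) / se_high)) if se_high > 0 else float("nan")
    return GroupRateModel(
        slopes={"low": b_day, "high": b_day + b_int},
        slope_se={"low": se_low, "high": se_high},
        slope_p={"low": float(pvals["day"]), "high": float(p_high)},
        interaction_p=float(pvals[inter_name]),
        method=method,
        cluster=cluster,
        n_clusters=int(n_clusters),
        flags=flags,
    )


def marginal_day_comparison(
    table: ObservationTable,
    metric: str,
    day: int,
    groups: Mapping[str, str],
    treatment: str | TreatmentLevel = "HT-HL",
    normalize_to_initial: bool = False,
) -> MarginalComparison:
    """Between-group comparison of a metric at one day.

    With ``normalize_to_initial`` each ramet's value is divided by its own
    day-0 (or earliest available baseline) value; ramets without a
    baseline are excluded with a warning.  The p-value uses colony-
    cluster-robust variance.
    """
    key = treatment if isinstance(treatment, str) else treatment.key
    temp, _, light = key.partition("-")
    df = table.df
    df = df[(df["temperature"] == temp) & (df["light"] == light) & df[metric].notna()].copy()
    df["group"] = df["species"].map(dict(groups))
    df = df[df["group"].isin(["low", "high"])]
    at_day = df[df["day"] == day].copy()
    if at_day.empty or at_day["group"].nunique() < 2:
        raise ValueError(f"both groups must be observed at day {day}")

    if normalize_to_initial:
        base = df[df["day"] <= 0].sort_values("day")
        base = base.groupby(["species", "colony", "ramet"], sort=False)[metric].first()
        vals, grp, cl = [], [], []
        dropped = 0
        for _, r in at_day.iterrows():
            k = (r["species"], r["colony"], r["ramet"])
            if k in base.index and base[k] != 0:
                vals.append(r[metric] / base[k])
                grp.append(r["group"])
                cl.append(f"{r['species']}/{r['colony']}")
            else:
                dropped += 1
        if dropped:
            warnings.warn(f"day {day}: excluded {dropped} ramet(s) without a baseline")
        work = pd.DataFrame({"y": vals, "group": grp, "cluster_id": cl})
    else:
        work = pd.DataFrame(
            {
                "y": at_day[metric].to_numpy(float),
                "group": at_day["group"].to_numpy(),
                "cluster_id": (at_day["species"] + "/" + at_day["colony"]).to_numpy(),
            }
        )
    work["group"] = pd.Categorical(work["group"], categories=["low", "high"])
    n_low = int((work["group"] == "low").sum())
    n_high = int((work["group"] == "high").sum())
    if n_low == 0 or n_high == 0:
        raise ValueError(f"both groups must be observed at day {day}")
    fit = smf.ols("y ~ C(group)", data=work).fit(
        cov_type="cluster", cov_kwds={"groups": work["cluster_id"]}, use_t=True
    )
    name = [k for k in fit.params.index if "group" in k][0]
    return MarginalComparison(
        day=day,
        difference=float(fit.params[name]),
        p=float(fit.pvalues[name]),
        n_low=n_low,
        n_high=n_high,
        normalized=normalize_to_initial,
    )


def baseline_compare(
    table: ObservationTable,
    metric: str,
    groups: Mapping[str, str],
) -> BaselineComparison:
    """Two-sample t-test on ramet-level pre-stress (day < 0) means
    between scattering groups.  Difference is mean(high) - mean(low)."""
    df = table.df
    df = df[(df["day"] < 0) & df[metric].notna()].copy()
    if df.empty:
        raise ValueError("no baseline (day < 0) observations")
    df["group"] = df["species"].map(dict(groups))
    df = df[df["group"].isin(["low", "high"])]
    ramet_means = (
        df.groupby(["species", "colony", "ramet", "temperature", "light", "group"],
                   sort=False, observed=True)[metric]
        .mean()
        .reset_index()
    )
    low = ramet_means.loc[ramet_means["group"] == "low", metric].to_numpy(float)
    high = ramet_means.loc[ramet_means["group"] == "high", metric].to_numpy(float)
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both groups need baseline observations")
    t, p = sps.ttest_ind(high, low)
    return BaselineComparison(
        difference=float(high.mean() - low.mean()),
        t=float(t), p=float(p), n_low=len(low), n_high=len(high),
    )
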