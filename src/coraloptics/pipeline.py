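"""End-to-end analysis stages shared by the CLI and the acceptance
harness: reflectance inversion over an observation table, per-pigment
absorption dynamics, the optical feedback statistic and its inverse-power
law, and the Phi_NPQ fold-change summary."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ObservationTable, OpticalProfile
from .optics import (
    AbsorptionParams,
    LOWER_BOUND,
    PowerLawFit,
    feedback_rate,
    fit_inverse_power_law,
    infer_absorption,
    per_pigment_dynamics,
)
from .stats import STRESS_WINDOW

__all__ = [
    "absorption_table",
    "species_absorption_dynamics",
    "FeedbackAnalysis",
    "feedback_power_law_analysis",
    "npq_fold_change",
]


def absorption_table(
    table: ObservationTable,
    profiles: Sequence[OpticalProfile],
    params: AbsorptionParams = LOWER_BOUND,
    pigment: str = "chla",
) -> pd.DataFrame:
    """Invert every observation with both R_H and pigment density into
    absorbed-light fractions (one row per observation)."""
    r_s = {p.species: p.r_s for p in profiles}
    df = table.df
    df = df[df["r_h"].notna() & df[pigment].notna()]
    rows = []
    for _, r in df.iterrows():
        if r["species"] not in r_s:
            continue
        res = infer_absorption(float(r["r_h"]), r_s[r["species"]], params)
        rows.append(
            {
                "species": r["species"], "colony": r["colony"], "ramet": r["ramet"],
                "temperature": r["temperature"], "light": r["light"], "day": int(r["day"]),
                "rho": float(r[pigment]),
                "i_a1": res.i_a1, "i_a2": res.i_a2, "i_a": res.i_a,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)


def species_absorption_dynamics(
    table: ObservationTable,
    profiles: Sequence[OpticalProfile],
    treatment: str,
    params: AbsorptionParams = LOWER_BOUND,
    pigment: str = "chla",
    window: tuple[int, int] = STRESS_WINDOW,
) -> pd.DataFrame:
    """Per-species stress-window dynamics under one treatment.

    Ramet values are averaged per species x day (mean R_H, mean pigment),
    the species-mean reflectance is inverted, and I_a2 per unit pigment is
    formed per day.  Returns columns species, day, rho, i_a1, i_a2, ratio.
    """
    r_s = {p.species: p.r_s for p in profiles}
    df = table.subset(treatment=treatment, window=window)
    df = df[df["r_h"].notna() & df[pigment].notna()]
    rows = []
    for (sp, day), sub in df.groupby(["species", "day"], sort=True):
        if sp not in r_s:
            continue
        r_h = float(sub["r_h"].mean())
        rho = float(sub[pigment].mean())
        if rho <= 0:
            continue
        res = infer_absorption(r_h, r_s[sp], params)
        rows.append(
            {
                "species": sp, "day": int(day), "rho": rho,
                "i_a1": res.i_a1, "i_a2": res.i_a2, "ratio": res.i_a2 / rho,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeedbackAnalysis:
    """Per-species feedback rates and the inverse-power-law fit."""

    rates: pd.DataFrame  # species, mu_sm, feedback_rate
    fit: PowerLawFit | None
    excluded: tuple[str, ...] = ()


def feedback_power_law_analysis(
    table: ObservationTable,
    profiles: Sequence[OpticalProfile],
    params: AbsorptionParams = LOWER_BOUND,
    pigment: str = "chla",
    window: tuple[int, int] = STRESS_WINDOW,
) -> FeedbackAnalysis:
    """Full optical-feedback pipeline.

    For each species, form the skeleton-dependent absorption per unit
    pigment I_a2/rho under HT-HL and HT-CL (species x day means), align
    the two series on shared days, and compute the feedback rate
    -d(I_a2/rho|HTHL - I_a2/rho|HTCL)/d(rho) against the HT-HL pigment
    series.  Species with a non-positive rate cannot enter the log-log
    fit and are excluded with a warning.
    """
    mu = {p.species: p.mu_sm for p in profiles}
    hl = species_absorption_dynamics(table, profiles, "HT-HL", params, pigment, window)
    cl = species_absorption_dynamics(table, profiles, "HT-CL", params, pigment, window)
    rows, excluded = [], []
    for sp in sorted(set(hl["species"]) & set(cl["species"])):
        a = hl[hl["species"] == sp].set_index("day")
        b = cl[cl["species"] == sp].set_index("day")
        days = a.index.intersection(b.index)
        if len(days) < 2:
            excluded.append(sp)
            continue
        rate = feedback_rate(
            a.loc[days, "ratio"].to_numpy(),
            b.loc[days, "ratio"].to_numpy(),
            a.loc[days, "rho"].to_numpy(),
        )
        rows.append({"species": sp, "mu_sm": mu[sp], "feedback_rate": rate})
    rates = pd.DataFrame(rows)
    fit = None
    if not rates.empty:
        positive = rates[rates["feedback_rate"] > 0]
        dropped = sorted(set(rates["species"]) - set(positive["species"]))
        if dropped:
            warnings.warn(f"non-positive feedback rate, excluded from power law: {dropped}")
            excluded.extend(dropped)
        if len(positive) >= 3:
            fit = fit_inverse_power_law(
                positive["mu_sm"].to_numpy(), positive["feedback_rate"].to_numpy()
            )
    return FeedbackAnalysis(rates=rates, fit=fit, excluded=tuple(excluded))


def npq_fold_change(
    table: ObservationTable,
    groups: Mapping[str, str],
    treatments: tuple[str, ...] = ("HT-CL", "HT-HL"),
) -> dict[str, float]:
    """Mean per-ramet post-stress / baseline Phi_NPQ ratio by group under
    thermal stress.  Ramets without both a baseline and a post-stress
    mean are skipped."""
    df = table.df
    keys = [t.partition("-") for t in treatments]
    mask = pd.Series(False, index=df.index)
    for temp, _, light in keys:
        mask |= (df["temperature"] == temp) & (df["light"] == light)
    df = df[mask & df["phi_npq"].notna()].copy()
    df["group"] = df["species"].map(dict(groups))
    folds: dict[str, list[float]] = {}
    for (grp, _sp, _col, _ram, _t, _l), sub in df.groupby(
        ["group", "species", "colony", "ramet", "temperature", "light"], sort=False
    ):
        base = sub.loc[sub["day"] < 0, "phi_npq"]
        post = sub.loc[sub["day"] >= 0, "phi_npq"]
        if base.empty or post.empty or base.mean() <= 0:
            continue
        folds.setdefault(grp, []).append(float(post.mean() / base.mean()))
    return {g: float(np.mean(v)) for g, v in folds.items()}
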