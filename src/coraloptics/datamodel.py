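"""Domain types for the coral optical-feedback bleaching analysis.

The experiment observes clonal coral fragments (ramets) from parent
colonies of several species under a 2 x 2 temperature x light factorial
design, sampled every second day through a pre-stress baseline and an
11-day stress window.  Each observation carries per-ramet bleaching
metrics (dark-adapted PSII yield Fv/Fm, maximum excitation pressure Qm,
pigment/symbiont areal density, chlorophyll a density, holobiont
reflectance R_H, and the non-photochemical quenching yield).  Per-species
skeletal optics (microscopic reduced scattering coefficient mu'_S,m,
skeletal reflectance R_S) live in :class:`OpticalProfile`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Group",
    "OpticalProfile",
    "TreatmentLevel",
    "TREATMENTS",
    "Observation",
    "ObservationTable",
    "ValidationIssue",
    "ValidationReport",
    "validate_observations",
    "METRIC_COLUMNS",
    "DEFAULT_WINDOW",
]

#: Metric columns an observation row may carry (at least one must be present).
METRIC_COLUMNS = ("fvfm", "qm", "rho", "chla", "r_h", "phi_npq")

#: Default experiment window: 10 baseline days before stress onset (day 0)
#: and 11 days of stress thereafter.
DEFAULT_WINDOW = (-10, 11)


class Group(str, enum.Enum):
    """Scattering group of a species: below (low) or at/above (high) the
    across-species mean of mu'_S,m."""

    LOW = "low"
    HIGH = "high"
    UNASSIGNED = "unassigned"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class OpticalProfile:
    """Per-species skeletal optical properties.

    Parameters
    ----------
    species:
        Species label.
    mu_sm:
        Microscopic reduced scattering coefficient mu'_S,m (mm^-1); the
        inverse distance a short-path photon travels in the top ~100-200 um
        of skeleton before direction randomization.
    mu_s_bulk:
        Bulk reduced scattering coefficient mu'_S (mm^-1), optional.
    r_s:
        Diffuse skeletal reflectance relative to a white standard, in (0, 1].
    tissue_thickness_mm:
        Host tissue thickness (mm), optional.
    group:
        Scattering group; derivable from mu_sm via
        :func:`coraloptics.stats.classify_scattering_group`.
    """

    species: str
    mu_sm: float
    r_s: float
    mu_s_bulk: float | None = None
    tissue_thickness_mm: float | None = None
    group: Group = Group.UNASSIGNED

    def __post_init__(self) -> None:
        if not self.mu_sm > 0:
            raise ValueError(f"{self.species}: mu_sm must be > 0, got {self.mu_sm}")
        if not (0 < self.r_s <= 1):
            raise ValueError(f"{self.species}: r_s must be in (0, 1], got {self.r_s}")
        if self.tissue_thickness_mm is not None and not self.tissue_thickness_mm > 0:
            raise ValueError(
                f"{self.species}: tissue_thickness_mm must be > 0 when present"
            )

    def with_group(self, group: Group) -> "OpticalProfile":
        return replace(self, group=group)


@dataclass(frozen=True)
class TreatmentLevel:
    """One cell of the temperature x light factorial design.

    Temperature is CT (control, nominal 26.2 degC) or HT (high, 32.3 degC);
    light is CL (control, 83 umol photons m^-2 s^-1) or HL (high, 328).
    """

    temperature: str
    light: str

    NOMINAL_TEMPERATURE_C = {"CT": 26.2, "HT": 32.3}
    NOMINAL_LIGHT_UMOL = {"CL": 83.0, "HL": 328.0}

    def __post_init__(self) -> None:
        if self.temperature not in ("CT", "HT"):
            raise ValueError(f"temperature must be CT or HT, got {self.temperature!r}")
        if self.light not in ("CL", "HL"):
            raise ValueError(f"light must be CL or HL, got {self.light!r}")

    @property
    def key(self) -> str:
        return f"{self.temperature}-{self.light}"

    @property
    def temperature_c(self) -> float:
        return self.NOMINAL_TEMPERATURE_C[self.temperature]

    @property
    def light_umol(self) -> float:
        return self.NOMINAL_LIGHT_UMOL[self.light]

    @classmethod
    def from_key(cls, key: str) -> "TreatmentLevel":
        temp, _, light = key.partition("-")
        return cls(temp, light)


#: The four treatment cells, in canonical order.
TREATMENTS = (
    TreatmentLevel("CT", "CL"),
    TreatmentLevel("CT", "HL"),
    TreatmentLevel("HT", "CL"),
    TreatmentLevel("HT", "HL"),
)


@dataclass
class Observation:
    """One ramet x day x treatment record of bleaching metrics.

    ``day`` is relative to stress onset (day 0); baseline days are negative.
    All metrics are optional (``None`` = not measured), but at least one
    must be present.
    """

    species: str
    colony: str
    ramet: str
    treatment: TreatmentLevel
    day: int
    fvfm: float | None = None
    qm: float | None = None
    rho: float | None = None
    chla: float | None = None
    r_h: float | None = None
    phi_npq: float | None = None

    def metrics(self) -> dict[str, float]:
        out = {}
        for m in METRIC_COLUMNS:
            v = getattr(self, m)
            if v is not None:
                out[m] = v
        return out


_DEFAULT_UNITS = {
    "fvfm": "dimensionless",
    "qm": "dimensionless",
    "rho": "ug Chl a cm^-2",
    "chla": "ug cm^-2",
    "r_h": "fraction of white standard",
    "phi_npq": "dimensionless",
}


class ObservationTable:
    """A long-format table of :class:`Observation` rows backed by a
    :class:`pandas.DataFrame`.

    One row per ramet x day x treatment; one column per metric; empty cell
    means the metric was not measured.  Metadata records units, the
    experiment window, and a free-text provenance note.
    """

    COLUMNS = ("species", "colony", "ramet", "temperature", "light", "day") + METRIC_COLUMNS

    def __init__(
        self,
        df: pd.DataFrame,
        units: Mapping[str, str] | None = None,
        window: tuple[int, int] = DEFAULT_WINDOW,
        provenance: str = "",
    ) -> None:
        missing = [c for c in ("species", "colony", "ramet", "temperature", "light", "day") if c not in df.columns]
        if missing:
            raise ValueError(f"observation table missing mandatory columns: {missing}")
        df = df.copy()
        for m in METRIC_COLUMNS:
            if m not in df.columns:
                df[m] = pd.NA
            df[m] = pd.to_numeric(df[m], errors="raise")
        df["day"] = df["day"].astype(int)
        self.df = df[list(self.COLUMNS)].reset_index(drop=True)
        self.units = dict(_DEFAULT_UNITS, **(units or {}))
        self.window = tuple(window)
        self.provenance = provenance

    @classmethod
    def from_observations(
        cls,
        observations: Iterable[Observation],
        units: Mapping[str, str] | None = None,
        window: tuple[int, int] = DEFAULT_WINDOW,
        provenance: str = "",
    ) -> "ObservationTable":
        rows = []
        for o in observations:
            rows.append(
                {
                    "species": o.species,
                    "colony": o.colony,
                    "ramet": o.ramet,
                    "temperature": o.treatment.temperature,
                    "light": o.treatment.light,
                    "day": o.day,
                    **{m: getattr(o, m) for m in METRIC_COLUMNS},
                }
            )
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)), units, window, provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Observation]:
        for _, r in self.df.iterrows():
            yield Observation(
                species=r["species"],
                colony=r["colony"],
                ramet=r["ramet"],
                treatment=TreatmentLevel(r["temperature"], r["light"]),
                day=int(r["day"]),
                **{m: (None if pd.isna(r[m]) else float(r[m])) for m in METRIC_COLUMNS},
            )

    def subset(
        self,
        treatment: TreatmentLevel | str | None = None,
        window: tuple[int, int] | None = None,
        species: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        """Filtered view of the underlying frame (copy)."""
        df = self.df
        if treatment is not None:
            key = treatment if isinstance(treatment, str) else treatment.key
            temp, _, light = key.partition("-")
            df = df[(df["temperature"] == temp) & (df["light"] == light)]
        if window is not None:
            df = df[(df["day"] >= window[0]) & (df["day"] <= window[1])]
        if species is not None:
            df = df[df["species"].isin(list(species))]
        return df.copy()


@dataclass(frozen=True)
class ValidationIssue:
    row: int | None
    field: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, row: int | None, field_: str, message: str) -> None:
        self.issues.append(ValidationIssue(row, field_, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def __str__(self) -> str:
        if self.ok:
            return "validation: OK"
        lines = [f"validation: {len(self.issues)} issue(s)"]
        for i in self.issues:
            where = f"row {i.row}" if i.row is not None else "table"
            lines.append(f"  {where} [{i.field}]: {i.message}")
        return "\n".join(lines)


def validate_observations(table: ObservationTable) -> ValidationReport:
    """Check range, uniqueness, and presence invariants without mutating
    the table.  The report is empty iff all invariants hold."""
    report = ValidationReport()
    df = table.df
    lo, hi = table.window
    present = df[list(METRIC_COLUMNS)].notna()

    for idx, has_any in present.any(axis=1).items():
        if not has_any:
            report.add(int(idx), "metrics", "no metric present")

    out_of_window = df.index[(df["day"] < lo) | (df["day"] > hi)]
    for idx in out_of_window:
        report.add(int(idx), "day", f"day {df.at[idx, 'day']} outside window [{lo}, {hi}]")

    for m, lo_v, hi_v in (
        ("fvfm", 0.0, 1.0),
        ("qm", None, None),  # Qm may exceed [0, 1]; flagged upstream, not here
        ("rho", 0.0, None),
        ("chla", 0.0, None),
        ("r_h", 0.0, None),
        ("phi_npq", 0.0, 1.0),
    ):
        vals = df[m]
        mask = vals.notna()
        if lo_v is not None:
            for idx in df.index[mask & (vals < lo_v)]:
                report.add(int(idx), m, f"{m} = {vals[idx]} < {lo_v}")
        if hi_v is not None:
            for idx in df.index[mask & (vals > hi_v)]:
                report.add(int(idx), m, f"{m} = {vals[idx]} > {hi_v}")

    key_cols = ["species", "colony", "ramet", "temperature", "light", "day"]
    for m in METRIC_COLUMNS:
        sub = df[df[m].notna()]
        dup = sub.duplicated(subset=key_cols, keep=False)
        if dup.any():
            for idx in sub.index[dup]:
                key = tuple(df.loc[idx, key_cols])
                report.add(int(idx), m, f"duplicate key {key} for metric {m}")
    return report
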