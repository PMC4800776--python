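"""Delimited-text readers and writers.

All external interfaces are UTF-8 CSV with a header row:

* observation tables: ``species, colony, ramet, temperature, light, day,
  fvfm, qm, rho, chla, r_h, phi_npq`` (empty cell = missing metric);
* optical profiles: ``species, mu_sm, mu_s_bulk, r_s, tissue_thickness_mm``
  (optionally ``group``);
* spectra: ``wavelength_nm, sample, standard, dark`` per measurement, or a
  long format with a leading ``measurement_id`` column;
* PAM induction curves: comment lines ``# f0=... fm=...`` followed by
  ``cycle, time_s, f_prime, fm_prime`` rows.

Readers never silently coerce malformed numbers: unparseable rows are
reported with their 1-based file line numbers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DEFAULT_WINDOW,
    METRIC_COLUMNS,
    Group,
    ObservationTable,
    OpticalProfile,
    validate_observations,
)
from .photophysiology import PAMRecord
from .reflectance import SpectralMeasurement

__all__ = [
    "read_observations",
    "write_observations",
    "read_optical_profiles",
    "write_optical_profiles",
    "read_spectrum",
    "read_spectra_long",
    "write_spectrum",
    "read_pam_record",
    "load_config_file",
]

_MANDATORY = ("species", "colony", "ramet", "temperature", "light", "day")
_MALFORMED = object()  # sentinel for unparseable numeric cells


class SchemaError(ValueError):
    """Header does not name the mandatory columns."""


class IntegrityError(ValueError):
    """Duplicate (species, colony, ramet, treatment, day) key for a metric."""


def read_observations(
    path: str | Path,
    units: Mapping[str, str] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    strict: bool = True,
) -> ObservationTable:
    """Read a long-format observation table from CSV.

    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`IntegrityError` on duplicate keys per metric.  Rows whose day
    falls outside ``window`` produce a warning listing the offending file
    lines.  Malformed numeric cells raise (no silent coercion) when
    ``strict``; otherwise they are reported and dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")
    unknown = [c for c in raw.columns if c not in ObservationTable.COLUMNS]
    if unknown:
        raise SchemaError(f"{path.name}: unknown columns {unknown}")

    def parse_cell(v):
        # Python float() is correctly rounded (pandas' fast parser is not,
        # which would break the bit-exact round-trip contract)
        if v is np.nan or v is None:
            return np.nan
        try:
            return float(v)
        except ValueError:
            return _MALFORMED

    bad_lines: list[tuple[int, str, str]] = []  # (file line, column, cell)
    numeric = {}
    for col in ("day",) + tuple(m for m in METRIC_COLUMNS if m in raw.columns):
        cells = raw[col].str.strip().replace("", np.nan)
        parsed = cells.map(parse_cell)
        malformed = parsed.map(lambda x: x is _MALFORMED)
        for idx in raw.index[malformed]:
            bad_lines.append((int(idx) + 2, col, raw.at[idx, col]))  # +2: header + 1-based
        numeric[col] = parsed.mask(malformed, np.nan).astype(float)
    if bad_lines:
        detail = "; ".join(f"line {ln}: {col}={cell!r}" for ln, col, cell in bad_lines)
        if strict:
            raise ValueError(f"{path.name}: unparseable numeric cells ({detail})")
        warnings.warn(f"{path.name}: dropping rows with unparseable cells ({detail})")
    df = raw.copy()
    for col, parsed in numeric.items():
        df[col] = parsed
    if bad_lines and not strict:
        drop = sorted({ln - 2 for ln, _, _ in bad_lines})
        df = df.drop(index=drop)
    if df["day"].isna().any():
        lines = [int(i) + 2 for i in df.index[df["day"].isna()]]
        raise ValueError(f"{path.name}: missing day values at lines {lines}")

    table = ObservationTable(df, units=units, window=window, provenance=f"read from {path}")

    key_cols = ["species", "colony", "ramet", "temperature", "light", "day"]
    for m in METRIC_COLUMNS:
        sub = table.df[table.df[m].notna()]
        dup = sub.duplicated(subset=key_cols, keep=False)
        if dup.any():
            first = tuple(
                v.item() if hasattr(v, "item") else v
                for v in sub.loc[sub.index[dup][0], key_cols]
            )
            raise IntegrityError(
                f"{path.name}: duplicate key {first} for metric {m!r} "
                f"({int(dup.sum())} rows involved)"
            )

    lo, hi = window
    outside = table.df.index[(table.df["day"] < lo) | (table.df["day"] > hi)]
    if len(outside):
        lines = [int(i) + 2 for i in outside]
        warnings.warn(
            f"{path.name}: {len(outside)} row(s) with day outside window "
            f"[{lo}, {hi}] at file lines {lines}"
        )
    return table


def write_observations(table: ObservationTable, path: str | Path) -> Path:
    """Write an observation table as CSV.  Floats are rendered with 17
    significant digits so a write/read round trip is value-exact."""
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_optical_profiles(path: str | Path) -> list[OpticalProfile]:
    df = pd.read_csv(path)
    if "species" not in df.columns or "mu_sm" not in df.columns or "r_s" not in df.columns:
        raise SchemaError(f"{Path(path).name}: profiles need species, mu_sm, r_s columns")
    profiles = []
    for _, r in df.iterrows():
        profiles.append(
            OpticalProfile(
                species=str(r["species"]),
                mu_sm=float(r["mu_sm"]),
                r_s=float(r["r_s"]),
                mu_s_bulk=float(r["mu_s_bulk"]) if "mu_s_bulk" in df.columns and pd.notna(r.get("mu_s_bulk")) else None,
                tissue_thickness_mm=float(r["tissue_thickness_mm"]) if "tissue_thickness_mm" in df.columns and pd.notna(r.get("tissue_thickness_mm")) else None,
                group=Group(r["group"]) if "group" in df.columns and pd.notna(r.get("group")) else Group.UNASSIGNED,
            )
        )
    return profiles


def write_optical_profiles(profiles: Sequence[OpticalProfile], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "species": [p.species for p in profiles],
            "mu_sm": [p.mu_sm for p in profiles],
            "mu_s_bulk": [p.mu_s_bulk for p in profiles],
            "r_s": [p.r_s for p in profiles],
            "tissue_thickness_mm": [p.tissue_thickness_mm for p in profiles],
            "group": [p.group.value for p in profiles],
        }
    ).to_csv(path, index=False, float_format="%.10g")
    return path


def read_spectrum(path: str | Path) -> SpectralMeasurement:
    """Read one spectral measurement (columns wavelength_nm, sample,
    standard, optional dark)."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "sample", "standard"):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: spectra need column {col!r}")
    return SpectralMeasurement(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        sample_counts=df["sample"].to_numpy(float),
        standard_counts=df["standard"].to_numpy(float),
        dark_counts=df["dark"].to_numpy(float) if "dark" in df.columns else None,
    )


def read_spectra_long(path: str | Path) -> dict[str, SpectralMeasurement]:
    """Read many measurements from a long table keyed by measurement_id."""
    df = pd.read_csv(path)
    if "measurement_id" not in df.columns:
        raise SchemaError(f"{Path(path).name}: long spectra need measurement_id")
    out = {}
    for mid, sub in df.groupby("measurement_id", sort=False):
        sub = sub.sort_values("wavelength_nm")
        out[str(mid)] = SpectralMeasurement(
            wavelengths=sub["wavelength_nm"].to_numpy(float),
            sample_counts=sub["sample"].to_numpy(float),
            standard_counts=sub["standard"].to_numpy(float),
            dark_counts=sub["dark"].to_numpy(float) if "dark" in df.columns else None,
        )
    return out


def write_spectrum(m: SpectralMeasurement, path: str | Path) -> Path:
    path = Path(path)
    cols = {
        "wavelength_nm": m.wavelengths,
        "sample": m.sample_counts,
        "standard": m.standard_counts,
    }
    if m.dark_counts is not None:
        cols["dark"] = m.dark_counts
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    return path


def read_pam_record(path: str | Path) -> PAMRecord:
    """Read a PAM induction-curve file.

    Dialect: leading comment lines ``# f0=<val>`` and ``# fm=<val>`` (or a
    single ``# f0=<val> fm=<val>``), then a CSV with header ``cycle,
    time_s, f_prime, fm_prime``.
    """
    path = Path(path)
    f0 = fm = None
    header_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            for tok in line.lstrip("#").replace(",", " ").split():
                key, _, val = tok.partition("=")
                if key == "f0":
                    f0 = float(val)
                elif key == "fm":
                    fm = float(val)
    if f0 is None or fm is None:
        raise SchemaError(f"{path.name}: PAM file needs '# f0=... fm=...' header lines")
    df = pd.read_csv(path, skiprows=header_lines)
    for col in ("time_s", "f_prime", "fm_prime"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: PAM file needs column {col!r}")
    induction = list(zip(df["time_s"].astype(float), df["f_prime"].astype(float), df["fm_prime"].astype(float)))
    return PAMRecord(f0=f0, fm=fm, induction=induction)


def load_config_file(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{Path(path).name}: config root must be a mapping")
    return cfg


# re-export for convenience
__all__.append("validate_observations")
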