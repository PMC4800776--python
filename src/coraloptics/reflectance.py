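"""Diffuse-reflectance processing: white-standard normalization, band
reduction to scalar reflectance, and replicate-spot aggregation.

Raw spectra are detector counts from a fiber spectrometer; reflectance at
each wavelength is the dark-corrected ratio to an adjacent white (PTFE)
standard.  No smoothing or filtering is applied anywhere: the value at a
wavelength depends only on that wavelength's inputs.  Per ramet and time
point, ten replicate spots are collected across the ramet geometry and
summarized by mean, standard error, and coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralMeasurement",
    "ReflectanceSpectrum",
    "ScalarReflectance",
    "normalize_spectrum",
    "scalar_reflectance",
    "aggregate_replicates",
    "minimal_resolvable_change",
    "VISIBLE_BAND",
]

#: Default reduction band (closed interval, nm): the visible range.
VISIBLE_BAND = (400.0, 700.0)


@dataclass(frozen=True)
class SpectralMeasurement:
    """Raw counts for one spot: sample, adjacent white standard, and an
    optional dark reading, all on a common strictly increasing
    wavelength grid."""

    wavelengths: np.ndarray
    sample_counts: np.ndarray
    standard_counts: np.ndarray
    dark_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, float)
        s = np.asarray(self.sample_counts, float)
        r = np.asarray(self.standard_counts, float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "sample_counts", s)
        object.__setattr__(self, "standard_counts", r)
        if self.dark_counts is not None:
            d = np.asarray(self.dark_counts, float)
            object.__setattr__(self, "dark_counts", d)
            if d.shape != w.shape:
                raise ValueError("dark_counts length mismatch")
            if np.any(d < 0):
                raise ValueError("dark counts must be >= 0")
        if w.ndim != 1 or len(w) < 2:
            raise ValueError("need at least 2 wavelengths")
        if s.shape != w.shape or r.shape != w.shape:
            raise ValueError("array length mismatch")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("sample counts must be >= 0")


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Dimensionless reflectance relative to the white standard, raw
    (unsmoothed) per the measurement protocol."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, float)
        r = np.asarray(self.reflectance, float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("reflectance must be finite and >= 0")


@dataclass(frozen=True)
class ScalarReflectance:
    """Replicate-aggregated scalar reflectance (role: holobiont R_H or
    bare-skeleton R_S)."""

    value: float
    n: int
    sem: float
    cov: float  # percent
    role: str = "holobiont R_H"
    flags: tuple[str, ...] = ()


def normalize_spectrum(m: SpectralMeasurement) -> ReflectanceSpectrum:
    """reflectance(lambda) = (sample - dark) / (standard - dark).

    Dark is taken as zero when absent.  Raises when the dark-corrected
    standard signal is not strictly positive anywhere in the spectrum.
    """
    dark = m.dark_counts if m.dark_counts is not None else 0.0
    denom = m.standard_counts - dark
    if np.any(denom <= 0):
        bad = m.wavelengths[np.asarray(denom <= 0).nonzero()[0]]
        raise ValueError(
            f"standard signal <= 0 after dark subtraction at wavelengths {bad[:5]}"
        )
    refl = (m.sample_counts - dark) / denom
    refl = np.clip(refl, 0.0, None)  # detector noise can dip below dark
    return ReflectanceSpectrum(m.wavelengths, refl)


def scalar_reflectance(
    s: ReflectanceSpectrum, band: tuple[float, float] = VISIBLE_BAND
) -> float:
    """Unweighted mean reflectance over the closed wavelength band."""
    lo, hi = band
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(
            f"band [{lo}, {hi}] nm has no overlap with spectrum "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] nm"
        )
    return float(np.mean(s.reflectance[mask]))


def aggregate_replicates(
    values: Sequence[float], role: str = "holobiont R_H"
) -> ScalarReflectance:
    """Mean, SEM (sample sd, n-1 denominator), and COV (%) of replicate
    spot values.  For n = 1 the sd is defined as 0 and flagged."""
    vals = np.asarray(list(values), float)
    n = len(vals)
    if n == 0:
        raise ValueError("need at least one replicate")
    mean = float(np.mean(vals))
    flags: tuple[str, ...] = ()
    if n == 1:
        sd = 0.0
        flags = ("single-replicate",)
    else:
        sd = float(np.std(vals, ddof=1))
    sem = sd / np.sqrt(n)
    cov = 100.0 * sd / mean if mean > 0 else 0.0
    return ScalarReflectance(value=mean, n=n, sem=float(sem), cov=float(cov), role=role, flags=flags)


def minimal_resolvable_change(agg: ScalarReflectance) -> float:
    """Smallest relative change (%) resolvable against replicate spread,
    operationalized as 2 * sem / mean * 100."""
    if agg.value <= 0:
        raise ValueError("mean reflectance must be > 0")
    return 200.0 * agg.sem / agg.value
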