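"""PAM chlorophyll-fluorometry derived photophysiology metrics.

Dark-adapted maximum quantum yield of PSII::

    Fv/Fm = (Fm - F0) / Fm

Steady-state yield partition from an induction curve, using the minimal
(F') and maximal (Fm') fluorescence under actinic light together with the
dark-adapted Fm::

    Phi_PSII = (Fm' - F') / Fm'      photochemistry
    Phi_NPQ  = F'/Fm' - F'/Fm        regulated non-photochemical quenching
    Phi_NO   = F'/Fm                 non-regulated dissipation

These three partition absorbed excitation energy and sum to 1 as an
algebraic identity.  Maximum excitation pressure over PSII::

    Qm = 1 - Phi_PSII(peak light) / (Fv/Fm at dawn)

Qm near 0 indicates light limitation (most PSII reaction centers open),
near 1 chronic photoinhibition (most centers closed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PAMRecord",
    "dark_yield",
    "induction_yields",
    "excitation_pressure",
    "DEFAULT_STEADY_CYCLES",
]

#: How many terminal induction cycles define "steady state" by default.
DEFAULT_STEADY_CYCLES = 3


@dataclass(frozen=True)
class PAMRecord:
    """One PAM measurement: dark-adapted F0/Fm plus an induction curve of
    (time_s, F', Fm') triples (13 cycles in the standard protocol)."""

    f0: float
    fm: float
    induction: Sequence[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not (self.fm >= self.f0 > 0):
            raise ValueError(f"need fm >= f0 > 0, got f0={self.f0}, fm={self.fm}")
        for i, (_, fp, fmp) in enumerate(self.induction):
            if not (fmp >= fp > 0):
                raise ValueError(
                    f"induction cycle {i}: need fm_prime >= f_prime > 0, "
                    f"got f_prime={fp}, fm_prime={fmp}"
                )

    @property
    def n_cycles(self) -> int:
        return len(self.induction)


def dark_yield(f0: float, fm: float) -> float:
    """Dark-adapted Fv/Fm = (fm - f0)/fm, in [0, 1)."""
    if not (fm >= f0 > 0):
        raise ValueError(f"need fm >= f0 > 0, got f0={f0}, fm={fm}")
    return (fm - f0) / fm


def induction_yields(
    record: PAMRecord, steady_cycles: int = DEFAULT_STEADY_CYCLES
) -> tuple[float, float, float]:
    """Partition the steady-state yield into (Phi_PSII, Phi_NPQ, Phi_NO).

    Steady-state F' and Fm' are means over the final ``steady_cycles``
    induction cycles.  The three components sum to 1 exactly (asserted to
    1e-12).
    """
    if not (1 <= steady_cycles <= record.n_cycles):
        raise ValueError(
            f"steady_cycles must be in [1, {record.n_cycles}], got {steady_cycles}"
        )
    tail = record.induction[-steady_cycles:]
    f_prime = float(np.mean([fp for _, fp, _ in tail]))
    fm_prime = float(np.mean([fmp for _, _, fmp in tail]))
    if fm_prime < f_prime:
        raise ValueError(
            f"steady-state Fm' ({fm_prime}) < F' ({f_prime}); invalid record"
        )
    phi_psii = (fm_prime - f_prime) / fm_prime
    phi_npq = f_prime / fm_prime - f_prime / record.fm
    phi_no = f_prime / record.fm
    assert abs(phi_psii + phi_npq + phi_no - 1.0) < 1e-12
    return phi_psii, phi_npq, phi_no


def excitation_pressure(phi_psii_peak: float, fvfm_dawn: float) -> float:
    """Maximum excitation pressure Qm = 1 - phi_psii_peak/fvfm_dawn.

    Values can fall outside [0, 1] when the peak-light yield exceeds the
    dawn yield; they are returned unclamped (callers may flag them).
    """
    if fvfm_dawn <= 0:
        raise ValueError(f"fvfm_dawn must be > 0, got {fvfm_dawn}")
    if phi_psii_peak < 0:
        raise ValueError(f"phi_psii_peak must be >= 0, got {phi_psii_peak}")
    return 1.0 - phi_psii_peak / fvfm_dawn
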