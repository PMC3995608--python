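"""Pulmonary vascular resistance estimators and hemodynamic ratios.

Three PVR estimates are implemented, all in Wood units (WU = mmHg·min/L):

* ``pvr_rhc`` — the invasive Ohm's-law reference, (mPAP − PCWP) / CO.
* ``pvr_cmr`` — the published MPA-velocity/RVEF regression model,
  ``19.38 − 4.62·ln(v̄_PA) − 0.08·RVEF``, with v̄_PA the cycle-averaged MPA mean
  velocity in cm/s and RVEF on the percent scale (the source model's published
  convention; this package's volumetry reports EF as a fraction, so convert
  with :func:`flow4d.volumetry.ef_percent`).
* ``pvr_4dflow`` — a linear model in the ratio of peak tricuspid regurgitation
  velocity to pulmonary flow, ``slope·(TRV/Q_P) + intercept``.  The shipped
  "paper" coefficients are (0.16, −7.25); a cohort-specific refit is preferred
  when fitting data exist, since a line derived under acute embolic conditions
  does not transfer to other etiologies.

The TRV/Q_P ratio has no universally agreed unit convention; here it defaults
to TRV in cm/s over Q_P in L/min, and every result records the convention used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("flow4d.hemodynamics")


class HemodynamicsError(ValueError):
    pass


#: Default unit convention for the TRV/Q_P ratio.
DEFAULT_RATIO_CONVENTION = "cm/s per L/min"

_RATIO_CONVENTIONS = {
    # name -> factor applied to (TRV[cm/s] / Q_P[L/min])
    "cm/s per L/min": 1.0,
    "m/s per L/min": 0.01,
    "cm/s per mL/cycle": None,  # requires heart rate; handled explicitly
}


@dataclass(frozen=True)
class PVRModelCoefficients:
    """Linear TRV/Q_P → PVR model, tagged with provenance and ratio convention."""

    slope: float  # WU per ratio unit
    intercept: float  # WU
    source: str = "paper"  # "paper" | "refit"
    ratio_convention: str = DEFAULT_RATIO_CONVENTION

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise HemodynamicsError("model coefficients must be finite")


#: The published acute-embolism line: PVR (WU) = 0.16 (TRV/Q_P) − 7.25.
PAPER_MODEL = PVRModelCoefficients(slope=0.16, intercept=-7.25, source="paper")


@dataclass
class HemodynamicRecord:
    """Per-measurement hemodynamics: catheter readings plus imaging estimates."""

    subject: str
    condition: str  # "pre" | "post"
    mpap: float  # mmHg
    pcwp: float  # mmHg
    co_thermodilution: float  # L/min
    trv: float | None = None  # cm/s
    qp_ml_cycle: float | None = None  # mL/cycle
    qp_l_min: float | None = None  # L/min
    qs_ml_cycle: float | None = None  # mL/cycle
    pvr_rhc: float | None = None  # WU
    pvr_cmr: float | None = None  # WU
    pvr_4dflow: float | None = None  # WU
    ratio_convention: str = DEFAULT_RATIO_CONVENTION

    def __post_init__(self) -> None:
        if self.mpap < 0 or self.pcwp < 0:
            raise HemodynamicsError("pressures must be nonnegative")


def pvr_rhc(mpap: float, pcwp: float, co: float) -> float:
    """Ohm's-law PVR (WU): trans-pulmonary gradient over flow.

    ``(mPAP − PCWP) / CO`` with pressures in mmHg and CO in L/min.  A wedge
    pressure above mPAP gives a negative value with a warning.
    """
    if co <= 0:
        raise HemodynamicsError("cardiac output must be positive")
    if mpap < pcwp:
        logger.warning("mPAP (%.1f) below PCWP (%.1f): negative PVR", mpap, pcwp)
    return (mpap - pcwp) / co


def pvr_cmr(pa_average_velocity: float, rvef_percent: float) -> float:
    """MPA-velocity/RVEF regression PVR (WU).

    ``19.38 − 4.62·ln(v)`` − ``0.08·RVEF`` with ``v`` the cycle-averaged MPA mean
    velocity in cm/s and RVEF in percent.
    """
    if pa_average_velocity <= 0:
        raise HemodynamicsError("PA average velocity must be positive")
    return 19.38 - 4.62 * np.log(pa_average_velocity) - 0.08 * rvef_percent


def pvr_4dflow(ratio: float, coeffs: PVRModelCoefficients = PAPER_MODEL) -> float:
    """Linear TRV/Q_P resistance estimate (WU): ``slope·ratio + intercept``."""
    if ratio < 0:
        raise HemodynamicsError("TRV/Q_P ratio must be nonnegative")
    return coeffs.slope * ratio + coeffs.intercept


def trv_qp_ratio(
    trv_cm_s: float,
    qp: float,
    convention: str = DEFAULT_RATIO_CONVENTION,
    heart_rate: float | None = None,
) -> tuple[float, str]:
    """TRV/Q_P under a named unit convention; returns (ratio, convention).

    Default: TRV in cm/s over Q_P in L/min.  The "cm/s per mL/cycle" convention
    takes ``qp`` in mL/cycle directly; the others take ``qp`` in L/min.
    """
    if convention not in _RATIO_CONVENTIONS:
        raise HemodynamicsError(
            f"unknown ratio convention {convention!r}; "
            f"known: {sorted(_RATIO_CONVENTIONS)}"
        )
    if qp <= 0:
        raise HemodynamicsError("Q_P must be positive")
    if convention == "cm/s per mL/cycle":
        return trv_cm_s / qp, convention
    return trv_cm_s / qp * _RATIO_CONVENTIONS[convention], convention


def bernoulli_gradient(trv_m_s: float) -> float:
    """Modified-Bernoulli pressure gradient, ``4 v²`` mmHg for v in m/s."""
    if trv_m_s < 0:
        raise HemodynamicsError("TRV must be nonnegative")
    return 4.0 * trv_m_s**2


def qp_qs(qp_ml_cycle: float, qs_ml_cycle: float) -> float:
    """Pulmonary-to-systemic flow ratio; ≈1 in a shunt-free circulation."""
    if qs_ml_cycle <= 0:
        raise HemodynamicsError("Q_S must be positive")
    return qp_ml_cycle / qs_ml_cycle


def relative_branch_flow(rpa_ml_cycle: float, lpa_ml_cycle: float) -> tuple[float, float]:
    """Right/left branch shares of total branch flow, in percent (sum = 100)."""
    total = rpa_ml_cycle + lpa_ml_cycle
    if total <= 0:
        raise HemodynamicsError("total branch flow must be positive")
    return 100.0 * rpa_ml_cycle / total, 100.0 * lpa_ml_cycle / total


def ml_cycle_to_l_min(net_ml_cycle: float, heart_rate: float) -> float:
    """Convert per-cycle flow (mL/cycle) to minute flow (L/min)."""
    return net_ml_cycle * heart_rate / 1000.0
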