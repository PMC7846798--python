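"""One-compartment intermittent-IV-infusion pharmacokinetics.

Closed-form concentration predictions for a drug given by repeated
constant-rate infusions, parameterized by clearance CL (L/h) and apparent
volume of distribution V (L).  Concentrations are in mg/L, which for
vancomycin equals the conventional TDM unit μg/ml (dose in mg, V in L).

Two routes to the same quantity are provided: the steady-state closed form
(:func:`conc_steady_state`) and finite-dose superposition
(:func:`conc_multidose`), which serves as an independent oracle and as the
predictor before steady state is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Regimen",
    "PKParams",
    "TDMRecord",
    "DOSING_MENU",
    "conc_single_dose",
    "conc_steady_state",
    "conc_multidose",
    "conc_ss_arrays",
    "trough_ss",
    "approach_peak_ss",
    "auc_ss",
]

TROUGH_OFFSET_H = 0.5   # troughs are drawn 0.5 h before the next dose
PEAK_OFFSET_H = 1.0     # "approach peak" is 1 h after the end of the infusion


class InvalidParameterError(ValueError):
    """Raised for nonpositive CL, V, dose or interval."""


class TimeDomainError(ValueError):
    """Raised when a requested sampling time falls outside the interval."""


@dataclass(frozen=True)
class Regimen:
    """An intermittent-infusion dosing schedule.

    Parameters
    ----------
    dose_mg : float
        Dose per administration (mg).
    interval_h : float
        Dosing interval τ (h); "qd" maps to 24 h.
    infusion_h : float
        Infusion duration Tinf (h); defaults to the standard 1 h.
    """

    dose_mg: float
    interval_h: float
    infusion_h: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise InvalidParameterError(f"dose must be >= 0, got {self.dose_mg}")
        if self.interval_h <= 0:
            raise InvalidParameterError(
                f"interval must be > 0, got {self.interval_h}"
            )
        if not (0 < self.infusion_h <= self.interval_h):
            raise InvalidParameterError(
                "infusion duration must lie in (0, interval], got "
                f"{self.infusion_h} for interval {self.interval_h}"
            )

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg * 24.0 / self.interval_h

    def label(self) -> str:
        g = self.dose_mg / 1000.0
        if self.interval_h == 24:
            return f"{g:g} g qd"
        return f"{g:g} g q{self.interval_h:g}h"


@dataclass(frozen=True)
class PKParams:
    """Individual or typical PK parameters: clearance and volume."""

    cl: float  # L/h
    v: float   # L

    def __post_init__(self) -> None:
        if not (self.cl > 0 and np.isfinite(self.cl)):
            raise InvalidParameterError(f"CL must be > 0, got {self.cl}")
        if not (self.v > 0 and np.isfinite(self.v)):
            raise InvalidParameterError(f"V must be > 0, got {self.v}")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V (1/h); derived, never stored."""
        return self.cl / self.v


@dataclass(frozen=True)
class TDMRecord:
    """One observed concentration with its sampling context."""

    patient_id: str
    time_in_interval_h: float  # since start of most recent infusion
    obs_type: str              # trough | approach_peak | other
    conc: float                # μg/ml
    at_steady_state: bool = True

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise InvalidParameterError(f"concentration must be >= 0, got {self.conc}")
        if self.obs_type not in ("trough", "approach_peak", "other"):
            raise InvalidParameterError(f"unknown obs_type {self.obs_type!r}")


#: The six regimens clinicians chose from in the source cohort.
DOSING_MENU: tuple[Regimen, ...] = (
    Regimen(500, 24.0),
    Regimen(500, 12.0),
    Regimen(500, 8.0),
    Regimen(500, 6.0),
    Regimen(1000, 24.0),
    Regimen(1000, 12.0),
)


def conc_single_dose(params: PKParams, regimen: Regimen, t):
    """Concentration after a single infusion started at t = 0.

    Vectorized over ``t``; returns 0 for t < 0.
    """
    t = np.asarray(t, dtype=float)
    k = params.k
    r0 = regimen.dose_mg / regimen.infusion_h  # mg/h
    tinf = regimen.infusion_h
    # -expm1 keeps 1 - exp(-x) accurate for small k*t
    during = (r0 / params.cl) * (-np.expm1(-k * np.minimum(t, tinf)))
    out = np.where(
        t < 0,
        0.0,
        during * np.exp(-k * np.maximum(t - tinf, 0.0)),
    )
    return out if out.ndim else float(out)


def conc_steady_state(params: PKParams, regimen: Regimen, t):
    """Steady-state concentration at time ``t`` within the dosing interval.

    ``t`` is measured from the start of the most recent infusion and must lie
    in [0, τ].  During the infusion,

        C(t) = (R0/CL)(1 − e^{−kt}) + C_ss(0) e^{−kt},

    and after it the profile decays mono-exponentially from

        C_ss(Tinf) = (R0/CL)(1 − e^{−k·Tinf}) / (1 − e^{−k·τ}).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > regimen.interval_h):
        raise TimeDomainError(
            f"t must lie in [0, {regimen.interval_h}] h, got {t}"
        )
    k = params.k
    r0 = regimen.dose_mg / regimen.infusion_h
    tinf = regimen.infusion_h
    tau = regimen.interval_h
    c_end = (r0 / params.cl) * (-np.expm1(-k * tinf)) / (-np.expm1(-k * tau))
    c_start = c_end * np.exp(-k * (tau - tinf))
    during = (r0 / params.cl) * (-np.expm1(-k * t)) + c_start * np.exp(-k * t)
    after = c_end * np.exp(-k * (t - tinf))
    out = np.where(t <= tinf, during, after)
    return out if out.ndim else float(out)


def conc_multidose(params: PKParams, regimen: Regimen, n_doses: int, t):
    """Superposition of ``n_doses`` single-infusion responses.

    ``t`` is measured from the start of the first infusion.  Converges to
    :func:`conc_steady_state` at matched phase as ``n_doses`` grows.
    """
    if n_doses < 1:
        raise InvalidParameterError(f"n_doses must be >= 1, got {n_doses}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise TimeDomainError("t must be >= 0")
    total = np.zeros_like(t, dtype=float)
    for j in range(n_doses):
        total = total + conc_single_dose(params, regimen, t - j * regimen.interval_h)
    return total if total.ndim else float(total)


def conc_ss_arrays(cl, v, dose, tau, tinf, t):
    """Vectorized steady-state concentration; no validation, numpy arrays.

    All arguments broadcast; intended for the estimation/simulation hot
    loops.  Semantics match :func:`conc_steady_state`.
    """
    cl = np.asarray(cl, float)
    k = cl / np.asarray(v, float)
    r0 = np.asarray(dose, float) / np.asarray(tinf, float)
    c_end = (r0 / cl) * (-np.expm1(-k * tinf)) / (-np.expm1(-k * tau))
    c_start = c_end * np.exp(-k * (tau - tinf))
    during = (r0 / cl) * (-np.expm1(-k * t)) + c_start * np.exp(-k * t)
    after = c_end * np.exp(-k * (t - tinf))
    return np.where(t <= tinf, during, after)


def trough_ss(params: PKParams, regimen: Regimen) -> float:
    """Steady-state trough: concentration 0.5 h before the next dose."""
    if regimen.interval_h <= TROUGH_OFFSET_H:
        raise TimeDomainError(
            f"interval must exceed {TROUGH_OFFSET_H} h for a trough sample"
        )
    return float(conc_steady_state(params, regimen, regimen.interval_h - TROUGH_OFFSET_H))


def approach_peak_ss(params: PKParams, regimen: Regimen) -> float:
    """Steady-state "approach peak": 1 h after the end of the infusion."""
    t = regimen.infusion_h + PEAK_OFFSET_H
    if t > regimen.interval_h:
        raise TimeDomainError(
            "infusion_duration + 1 h must not exceed the dosing interval"
        )
    return float(conc_steady_state(params, regimen, t))


def sample_time(regimen: Regimen, obs_type: str) -> float:
    """Within-interval sampling time for a named observation type."""
    if obs_type == "trough":
        return regimen.interval_h - TROUGH_OFFSET_H
    if obs_type == "approach_peak":
        return regimen.infusion_h + PEAK_OFFSET_H
    raise InvalidParameterError(f"no canonical time for obs_type {obs_type!r}")


def auc_ss(params: PKParams, regimen: Regimen) -> float:
    """Analytic AUC over one steady-state interval: dose/CL (mg·h/L)."""
    return regimen.dose_mg / params.cl
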