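"""Specific loss power (SLP) estimation from calorimetry traces.

The heating efficiency of a ferrofluid under an alternating magnetic
field is estimated by the initial-slope method: the temperature rise
rate just after field-on, corrected for pre-field baseline drift, gives

    SLP = C_s m_s (dT/dt) / m_Fe     [W per g of iron]

Extrapolation between field conditions uses linear-response f H^2
scaling and is flagged as model-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FieldCondition",
    "CalorimetryTrace",
    "SlpEstimate",
    "estimate_slope",
    "slp_from_slope",
    "estimate_slp",
    "extrapolate_lrt",
]


@dataclass(frozen=True)
class FieldCondition:
    """Alternating magnetic field drive condition."""

    frequency_khz: float
    amplitude_ka_m: float

    def __post_init__(self):
        if self.frequency_khz <= 0 or self.amplitude_ka_m <= 0:
            raise ValueError("frequency and amplitude must be positive")


#: Benchtop calorimeter condition used to characterise the particles.
CALORIMETER_CONDITION = FieldCondition(frequency_khz=515.0, amplitude_ka_m=15.0)
#: In vivo coil condition.
IN_VIVO_CONDITION = FieldCondition(frequency_khz=624.0, amplitude_ka_m=13.0)


@dataclass
class CalorimetryTrace:
    times: np.ndarray  # s
    temperatures: np.ndarray  # degC
    field_on_time: float  # s
    solution_mass_kg: float
    iron_mass_kg: float
    solution_heat_capacity: float = 4180.0  # J/(kg K), aqueous ferrofluid
    condition: FieldCondition = CALORIMETER_CONDITION

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.temperatures.shape:
            raise ValueError("times and temperatures must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.solution_mass_kg <= 0 or self.iron_mass_kg < 0:
            raise ValueError("masses must be positive")


@dataclass
class SlpEstimate:
    slp: float  # W/g(Fe)
    slope: float  # K/s
    fit_window: tuple[float, float]  # s
    condition: FieldCondition
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return {
            "slp_w_per_g": float(self.slp),
            "slope_k_per_s": float(self.slope),
            "fit_window_s": [float(self.fit_window[0]), float(self.fit_window[1])],
            "frequency_khz": self.condition.frequency_khz,
            "amplitude_ka_m": self.condition.amplitude_ka_m,
            "model_based_extrapolation": bool(self.extrapolated),
        }


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 2:
        return 0.0
    return float(np.polyfit(t, y, 1)[0])


def estimate_slope(trace: CalorimetryTrace, window: float = 10.0,
                   baseline_window: float = 10.0) -> float:
    """Initial heating slope (K/s) after field-on, baseline-corrected.

    OLS slope over [field_on, field_on + window] minus the OLS drift
    slope over [field_on - baseline_window, field_on).  Requires at
    least 5 samples in the heating window.
    """
    t0 = trace.field_on_time
    sel = (trace.times >= t0) & (trace.times <= t0 + window)
    if sel.sum() < 5:
        raise ValueError("heating window has fewer than 5 samples or lies outside the trace")
    slope = _ols_slope(trace.times[sel], trace.temperatures[sel])
    pre = (trace.times >= t0 - baseline_window) & (trace.times < t0)
    drift = _ols_slope(trace.times[pre], trace.temperatures[pre]) if pre.sum() >= 2 else 0.0
    return slope - drift


def slp_from_slope(slope: float, trace: CalorimetryTrace,
                   window: tuple[float, float] | None = None) -> SlpEstimate:
    """SLP = C_s m_s slope / m_Fe, in W per gram of iron."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if trace.iron_mass_kg <= 0:
        raise ValueError("iron mass must be positive")
    iron_mass_g = trace.iron_mass_kg * 1e3
    slp = trace.solution_heat_capacity * trace.solution_mass_kg * slope / iron_mass_g
    if window is None:
        window = (trace.field_on_time, trace.field_on_time + 10.0)
    return SlpEstimate(slp=float(slp), slope=float(slope), fit_window=window,
                       condition=trace.condition)


def estimate_slp(trace: CalorimetryTrace, window: float = 10.0) -> SlpEstimate:
    """Initial-slope SLP estimate for one trace."""
    slope = estimate_slope(trace, window=window)
    return slp_from_slope(slope, trace, window=(trace.field_on_time, trace.field_on_time + window))


def extrapolate_lrt(est: SlpEstimate, target: FieldCondition) -> SlpEstimate:
    """Linear-response scaling of SLP between field conditions.

    SLP_target = SLP_source x (f_t/f_s) x (H_t/H_s)^2.  This is a
    small-amplitude approximation, not a hysteresis-model prediction;
    the result is flagged as model-based extrapolation.
    """
    src = est.condition
    factor = (target.frequency_khz / src.frequency_khz) * (target.amplitude_ka_m / src.amplitude_ka_m) ** 2
    return replace(est, slp=est.slp * factor, condition=target, extrapolated=True)
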