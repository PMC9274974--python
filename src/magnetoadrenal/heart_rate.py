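"""Heart-rate analysis stage.

Pulse-oximetry heart-rate traces recorded around a magnetothermal
stimulation window (default 300-360 s into the session) contain gaps
from animal movement and signal loss.  The stage imputes the gaps by
Kalman smoothing under a local-level Gaussian state-space model, scales
every sample to the pre-stimulation baseline, averages the two
pre-conditioning session days pointwise, sums the stimulation-window
samples into an AUC, and compares conditions with a gamma GLM (identity
link) on the AUCs.

The local-level filter/smoother is implemented here directly (scalar
recursions, concentrated maximum likelihood over the signal-to-noise
ratio) so that a trace is imputed in milliseconds; it is the standard
model behind "Kalman smoothing with default parameters" in time-series
imputation packages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from . import stats

__all__ = [
    "HeartRateTrace",
    "ScaledTrace",
    "AucResult",
    "impute_gaps",
    "scale_baseline",
    "average_sessions",
    "auc_window",
    "compare_auc",
    "local_level_smooth",
]

DEFAULT_STIM_WINDOW = (300.0, 360.0)


@dataclass
class HeartRateTrace:
    """A bpm time series (uniform sampling, NaN = missing)."""

    times: np.ndarray  # s
    bpm: np.ndarray  # NaN where missing
    stim_window: tuple[float, float] = DEFAULT_STIM_WINDOW
    rat: str = ""
    day: int = 1
    condition: str = "control"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.times.shape != self.bpm.shape or self.times.ndim != 1:
            raise ValueError("times and bpm must be matching 1-D arrays")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("times must be uniformly sampled")
        lo, hi = self.stim_window
        if lo < self.times[0] or hi > self.times[-1]:
            raise ValueError("stimulation window must lie within the record")
        obs = self.bpm[np.isfinite(self.bpm)]
        if obs.size and np.any(obs <= 0):
            raise ValueError("observed bpm must be positive")

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.bpm)))


@dataclass
class ScaledTrace:
    """Ratio-to-baseline heart rate (dimensionless)."""

    times: np.ndarray
    values: np.ndarray
    baseline_bpm: float
    stim_window: tuple[float, float] = DEFAULT_STIM_WINDOW
    rat: str = ""
    day: int = 1
    condition: str = "control"


@dataclass
class AucResult:
    rat: str
    condition: str
    auc: float
    window: tuple[float, float]
    n_samples: int

    def to_dict(self) -> dict:
        return {"rat": self.rat, "condition": self.condition, "auc": float(self.auc),
                "window_s": [float(self.window[0]), float(self.window[1])],
                "n_samples": int(self.n_samples)}


def _local_level_loglik(log_q: float, y: np.ndarray) -> float:
    """Negative concentrated log-likelihood of the local-level model."""
    q = np.exp(log_q)
    obs = np.isfinite(y)
    first = int(np.argmax(obs))
    a = y[first]
    P = 1e7
    ssq, logF, n_obs = 0.0, 0.0, 0
    for t in range(first + 1, y.size):
        P = P + q
        if obs[t]:
            F = P + 1.0
            v = y[t] - a
            ssq += v * v / F
            logF += np.log(F)
            n_obs += 1
            Kg = P / F
            a = a + Kg * v
            P = P * (1.0 - Kg)
    if n_obs == 0:
        return 0.0
    sig2 = ssq / n_obs
    return 0.5 * (logF + n_obs * (np.log(max(sig2, 1e-300)) + 1.0))


def local_level_smooth(y: np.ndarray) -> np.ndarray:
    """Fixed-interval smoothed level of a local-level model fitted by
    maximum likelihood (concentrated over the signal-to-noise ratio).

    ``y`` may contain NaNs; returns the smoothed level at every index.
    """
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(y)
    if obs.sum() < 3:
        raise ValueError("need at least 3 observed samples")
    res = minimize_scalar(_local_level_loglik, bounds=(-12.0, 8.0), args=(y,),
                          method="bounded", options={"xatol": 1e-3})
    q = float(np.exp(res.x))

    n = y.size
    first = int(np.argmax(obs))
    a_pred = np.empty(n)
    P_pred = np.empty(n)
    a_filt = np.empty(n)
    P_filt = np.empty(n)
    a, P = y[first], 1e7
    for t in range(n):
        if t > first:
            P = P + q
        a_pred[t], P_pred[t] = a, P
        if obs[t] and t >= first:
            F = P + 1.0
            Kg = P / F
            a = a + Kg * (y[t] - a)
            P = P * (1.0 - Kg)
        a_filt[t], P_filt[t] = a, P

    # Rauch-Tung-Striebel backward pass (random-walk transition)
    sm = np.empty(n)
    sm[-1] = a_filt[-1]
    for t in range(n - 2, -1, -1):
        denom = P_filt[t] + q
        C = P_filt[t] / denom if denom > 0 else 0.0
        sm[t] = a_filt[t] + C * (sm[t + 1] - a_pred[t + 1])
    return sm


def impute_gaps(trace: HeartRateTrace, max_missing: float = 0.5,
                edge_window_s: float = 10.0) -> HeartRateTrace:
    """Fill missing samples by local-level Kalman smoothing.

    Observed samples are returned unchanged.  Traces with more than
    ``max_missing`` missing, or with no observation in the first or
    last ``edge_window_s`` seconds, are rejected (mirroring the study's
    "unable to impute" exclusions).
    """
    obs = np.isfinite(trace.bpm)
    if not obs.any():
        raise ValueError("unable to impute: all samples missing")
    if trace.missing_fraction > max_missing:
        raise ValueError(
            f"unable to impute: {trace.missing_fraction:.0%} missing exceeds {max_missing:.0%}"
        )
    t0, t1 = trace.times[0], trace.times[-1]
    if not obs[trace.times <= t0 + edge_window_s].any() or not obs[trace.times >= t1 - edge_window_s].any():
        raise ValueError("unable to impute: no observation within the edge windows")
    if obs.all():
        return replace(trace, bpm=trace.bpm.copy())
    level = local_level_smooth(trace.bpm)
    filled = np.where(obs, trace.bpm, level)
    return replace(trace, bpm=filled)


def scale_baseline(trace: HeartRateTrace) -> ScaledTrace:
    """Divide every sample by the mean pre-stimulation heart rate."""
    if np.any(~np.isfinite(trace.bpm)):
        raise ValueError("trace has missing values; run impute_gaps first")
    pre = trace.times < trace.stim_window[0]
    if not pre.any():
        raise ValueError("pre-stimulation segment is empty")
    baseline = float(np.mean(trace.bpm[pre]))
    if baseline <= 0:
        raise ValueError("non-positive baseline heart rate")
    return ScaledTrace(times=trace.times.copy(), values=trace.bpm / baseline,
                       baseline_bpm=baseline, stim_window=trace.stim_window,
                       rat=trace.rat, day=trace.day, condition=trace.condition)


def average_sessions(traces: list[ScaledTrace]) -> ScaledTrace:
    """Pointwise mean of same-length scaled traces (e.g. days 1 and 2)."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise ValueError("traces have mismatched time bases")
    values = np.mean([tr.values for tr in traces], axis=0)
    first = traces[0]
    return ScaledTrace(times=t0.copy(), values=values,
                       baseline_bpm=float(np.mean([tr.baseline_bpm for tr in traces])),
                       stim_window=first.stim_window, rat=first.rat, day=first.day,
                       condition=first.condition)


def auc_window(trace: ScaledTrace, window: tuple[float, float] | None = None) -> AucResult:
    """Sum of scaled samples over the stimulation window, endpoints
    inclusive (61 samples for 300-360 s at 1 Hz)."""
    lo, hi = window if window is not None else trace.stim_window
    sel = (trace.times >= lo) & (trace.times <= hi)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("stimulation window contains no samples")
    return AucResult(rat=trace.rat, condition=trace.condition,
                     auc=float(trace.values[sel].sum()), window=(lo, hi), n_samples=n)


def compare_auc(results: list[AucResult], active_label: str = "active") -> stats.GammaGlmFit:
    """Gamma GLM (identity link) of AUC on treatment condition."""
    if not results:
        raise ValueError("no AUC results")
    conditions = {r.condition for r in results}
    if len(conditions) < 2:
        raise ValueError("both conditions must be represented")
    y = np.array([r.auc for r in results], dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma GLM requires positive AUC values")
    active = np.array([1.0 if r.condition == active_label else 0.0 for r in results])
    X = np.column_stack([np.ones_like(active), active])
    return stats.fit_gamma_glm_identity(y, X, names=["intercept", "condition_active"])
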