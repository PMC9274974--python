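"""Freezing-behavior stage of the conditioning/extinction paradigm.

Per-trial freezing (fraction of the 30 s tone spent immobile) is
recorded over four phases: habituation (5 tone-alone trials),
conditioning (7 tone+shock trials), extinction (20 tone-alone trials)
and recall (3 tone-alone trials).  The normalization chain is, per rat:

1. per-phase min-max normalization (x - min)/(max - min);
2. division by the rat's baseline, the mean of normalized habituation
   trials 3-5 (values above 1 are clipped back into [0, 1] and the clip
   count reported);
3. centered moving average, window 3, windows shrunk at phase ends;
4. boundary compression (y (n-1) + 0.5)/n so exact 0s and 1s become
   admissible beta-regression responses.

Rats that never acquired the conditioned response are excluded by an
explicit criterion (late-conditioning freezing must exceed habituation
freezing by a configurable margin) standing in for the study's blinded
visual inspection.  The cohort model is a beta regression on trial,
phase, treatment and all their interactions; the extinction endpoint
(mean of trials 18-20) is compared between conditions with a Welch
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats

__all__ = [
    "PHASES",
    "TRIALS_PER_PHASE",
    "FreezingSeries",
    "NormalizedFreezing",
    "ConditioningCheck",
    "normalize_chain",
    "detect_nonconditioners",
    "fit_freezing_model",
    "extinction_endpoint_test",
    "moving_average_centered",
]

PHASES = ("habituation", "conditioning", "extinction", "recall")
TRIALS_PER_PHASE = {"habituation": 5, "conditioning": 7, "extinction": 20, "recall": 3}


@dataclass
class FreezingSeries:
    """Raw per-trial freezing fractions for one rat."""

    rat: str
    condition: str
    phases: dict  # phase -> 1-D array of fractions in [0, 1]

    def __post_init__(self):
        for name in PHASES:
            if name not in self.phases:
                raise ValueError(f"missing phase '{name}'")
            arr = np.asarray(self.phases[name], dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name}: freezing fractions must lie in [0, 1]")
            if arr.size != TRIALS_PER_PHASE[name]:
                raise ValueError(
                    f"{name}: expected {TRIALS_PER_PHASE[name]} trials, got {arr.size}"
                )
            self.phases[name] = arr

    @classmethod
    def from_percentages(cls, rat, condition, phases_percent: dict) -> "FreezingSeries":
        return cls(rat=rat, condition=condition,
                   phases={k: np.asarray(v, dtype=float) / 100.0 for k, v in phases_percent.items()})


@dataclass
class NormalizedFreezing:
    rat: str
    condition: str
    values: dict  # phase -> compressed values in (0, 1)
    smoothed: dict  # phase -> pre-compression smoothed values in [0, 1]
    baseline: float
    clip_count: int
    compression_n: int
    degenerate_phases: list = field(default_factory=list)


def moving_average_centered(x: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with windows shrunk to the available
    neighbors at the ends (no padding)."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def normalize_chain(series: FreezingSeries, baseline_trials: tuple[int, int] = (3, 5),
                    window: int = 3) -> NormalizedFreezing:
    """Run the full normalization chain on one rat's series.

    A phase with max == min cannot be min-max normalized; it is mapped
    to a constant 0.5 and flagged in ``degenerate_phases``.
    """
    normalized = {}
    degenerate = []
    for name in PHASES:
        x = series.phases[name]
        rng = x.max() - x.min()
        if rng == 0.0:
            normalized[name] = np.full_like(x, 0.5)
            degenerate.append(name)
        else:
            normalized[name] = (x - x.min()) / rng

    lo, hi = baseline_trials
    baseline = float(np.mean(normalized["habituation"][lo - 1:hi]))
    clip_count = 0
    scaled = {}
    for name in PHASES:
        if baseline > 0:
            v = normalized[name] / baseline
        else:
            v = normalized[name].copy()
        clipped = np.clip(v, 0.0, 1.0)
        clip_count += int(np.sum(clipped != v))
        scaled[name] = clipped

    smoothed = {name: moving_average_centered(scaled[name], window) for name in PHASES}
    n_total = int(sum(v.size for v in smoothed.values()))
    compressed = {name: (v * (n_total - 1) + 0.5) / n_total for name, v in smoothed.items()}
    return NormalizedFreezing(rat=series.rat, condition=series.condition,
                              values=compressed, smoothed=smoothed,
                              baseline=baseline, clip_count=clip_count,
                              compression_n=n_total, degenerate_phases=degenerate)


@dataclass
class ConditioningCheck:
    rat: str
    conditioned: bool
    late_conditioning_mean: float
    habituation_mean: float
    margin: float
    threshold: float

    def to_dict(self) -> dict:
        return {"rat": self.rat, "conditioned": bool(self.conditioned),
                "late_conditioning_mean": self.late_conditioning_mean,
                "habituation_mean": self.habituation_mean,
                "margin": self.margin, "threshold": self.threshold}


def detect_nonconditioners(series: FreezingSeries, threshold: float = 0.10) -> ConditioningCheck:
    """Flag rats that never acquired the conditioned response.

    Conditioned iff the mean raw freezing over the last 3 conditioning
    trials exceeds the mean habituation freezing by at least
    ``threshold`` (>= comparison: a rat exactly at the threshold counts
    as conditioned).
    """
    hab = float(np.mean(series.phases["habituation"]))
    late = float(np.mean(series.phases["conditioning"][-3:]))
    margin = late - hab
    return ConditioningCheck(rat=series.rat, conditioned=margin >= threshold,
                             late_conditioning_mean=late, habituation_mean=hab,
                             margin=margin, threshold=threshold)


def _design_row(trial: int, phase: str, treat: float) -> list[float]:
    ph = [1.0 if phase == p else 0.0 for p in PHASES[1:]]  # habituation = reference
    t = float(trial)
    row = [1.0, t] + ph + [treat]
    row += [t * p for p in ph]  # trial x phase
    row += [t * treat]  # trial x treatment
    row += [p * treat for p in ph]  # phase x treatment
    row += [t * p * treat for p in ph]  # trial x phase x treatment
    return row


def design_column_names() -> list[str]:
    ph = [f"phase_{p}" for p in PHASES[1:]]
    names = ["intercept", "trial"] + ph + ["treatment"]
    names += [f"trial:{p}" for p in ph]
    names += ["trial:treatment"]
    names += [f"{p}:treatment" for p in ph]
    names += [f"trial:{p}:treatment" for p in ph]
    return names


def fit_freezing_model(cohort: list[NormalizedFreezing],
                       active_label: str = "active") -> stats.BetaRegFit:
    """Beta regression of compressed freezing on trial, phase, treatment
    and all 2- and 3-way interactions.

    Trial index restarts at 1 within each phase; habituation is the
    reference phase.
    """
    conditions = {r.condition for r in cohort}
    if len(conditions) < 2 or min(
        sum(r.condition == c for r in cohort) for c in conditions
    ) < 2:
        raise ValueError("need at least 2 rats per condition after exclusions")
    rows, ys = [], []
    for rat in cohort:
        treat = 1.0 if rat.condition == active_label else 0.0
        for phase in PHASES:
            for j, y in enumerate(rat.values[phase], start=1):
                rows.append(_design_row(j, phase, treat))
                ys.append(y)
    X = np.asarray(rows)
    y = np.asarray(ys)
    names = design_column_names()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the collinear columns for the error message
        q, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    return stats.fit_beta_regression(y, X, names=names)


def extinction_endpoint_test(cohort: list[NormalizedFreezing],
                             trials: tuple[int, int] = (18, 20),
                             active_label: str = "active",
                             variant: str = "welch") -> stats.TTestResult:
    """Welch t-test of the per-rat mean freezing over the final
    extinction trials (18-20) between conditions."""
    lo, hi = trials
    active, control = [], []
    for rat in cohort:
        ext = rat.values["extinction"]
        if ext.size < hi:
            raise ValueError(f"rat {rat.rat}: extinction has fewer than {hi} trials")
        m = float(np.mean(ext[lo - 1:hi]))
        (active if rat.condition == active_label else control).append(m)
    return stats.t_test(active, control, variant=variant)
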