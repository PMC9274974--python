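"""Seeded synthetic rat cohort emulating every input the pipeline reads.

The generator produces, per rat: heart-rate traces with stimulation-
locked rises and dropout gaps (days 1, 2 pre-conditioning and day 4
post-conditioning), ELISA plate tables for two hormones on two
collection days (standards plus pre/post sample optical densities
through a known 4PL curve), per-trial freezing series through
habituation/conditioning/extinction/recall, adrenal section mask pairs,
and calorimetry traces.  Distributional families match what the
analyses assume: gamma-like AUCs, log-normal hormone baselines and
post/pre ratios, beta-distributed freezing around latent trial curves.

Every generated quantity's latent truth is stored on the
:class:`RatRecord`, so consuming stages can be tested against ground
truth.  A fixed seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import FreezingSeries, PHASES, TRIALS_PER_PHASE
from .calorimetry import CalorimetryTrace, CALORIMETER_CONDITION
from .heart_rate import HeartRateTrace, DEFAULT_STIM_WINDOW
from .histology import SectionMask
from .hormones import forward_4pl

__all__ = [
    "HeartRateModel",
    "HormoneModel",
    "FreezingModel",
    "HistologyModel",
    "CalorimetryModel",
    "CohortConfig",
    "RatRecord",
    "gen_heart_rate",
    "gen_hormones",
    "gen_freezing",
    "gen_section_masks",
    "gen_calorimetry",
    "gen_cohort",
    "write_cohort",
]


@dataclass
class HeartRateModel:
    baseline_bpm_mean: float = 360.0
    baseline_bpm_sd: float = 25.0
    stim_rise_fraction: float = 0.10  # active rats, pre-conditioning
    rise_sd: float = 0.05  # per-rat biological spread of the response
    day4_blunting: float = 0.1  # fraction of the rise left post-conditioning
    gap_rate: float = 0.10
    noise_sd_bpm: float = 5.0
    duration_s: float = 420.0
    sample_rate_hz: float = 1.0


@dataclass
class HormoneModel:
    # log-normal baselines (per-hormone mean of log concentration)
    baseline_log_mean: dict = field(default_factory=lambda: {"corticosterone": np.log(150.0), "epinephrine": np.log(1.5)})
    baseline_log_sd: float = 0.35
    # condition-specific multiplicative post/pre effects
    post_pre_effect: dict = field(default_factory=lambda: {"active": 0.7, "control": 1.0})
    ratio_log_sd: float = 0.3
    n_days: int = 2
    # latent 4PL plate curves (a, b, c, d) per hormone
    plate_curves: dict = field(default_factory=lambda: {
        "corticosterone": (0.08, 1.1, 180.0, 2.4),
        "epinephrine": (0.06, 1.2, 2.0, 2.1),
    })
    od_noise_sd: float = 0.0


@dataclass
class FreezingModel:
    habituation_level: float = 0.05
    acquisition_rate: float = 0.6  # conditioning 1 - exp(-k trial)
    asymptote: float = 0.8
    extinction_floor: float = 0.15
    extinction_decay: float = 0.15  # per trial, control rats
    treatment_decay_modifier: float = 1.0  # multiplies decay in active rats
    precision: float = 30.0  # beta observation precision
    non_acquirer_fraction: float = 0.1


@dataclass
class HistologyModel:
    image_shape: tuple = (192, 192)
    semi_axes_px: tuple = (80.0, 36.0)
    zone_probs: dict = field(default_factory=lambda: {"medulla": 0.35, "ZR": 0.40, "ZF": 0.25, "ZG": 0.0})
    n_blobs: int = 4
    blob_radius_px: float = 3.0
    bands: tuple = (0.4, 0.7, 0.9)


@dataclass
class CalorimetryModel:
    true_slp: float = 880.0  # W/g(Fe)
    solution_mass_kg: float = 1e-3
    iron_mass_kg: float = 2.5e-7
    solution_heat_capacity: float = 4180.0
    noise_sd_k: float = 0.05
    field_on_s: float = 30.0
    duration_s: float = 60.0
    start_temp_c: float = 25.0
    sample_rate_hz: float = 10.0  # optical-fiber probe logging rate


@dataclass
class CohortConfig:
    n_per_condition: int = 14
    seed: int = 0
    heart_rate: HeartRateModel = field(default_factory=HeartRateModel)
    hormones: HormoneModel = field(default_factory=HormoneModel)
    freezing: FreezingModel = field(default_factory=FreezingModel)
    histology: HistologyModel = field(default_factory=HistologyModel)
    calorimetry: CalorimetryModel = field(default_factory=CalorimetryModel)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["histology"]["image_shape"] = list(self.histology.image_shape)
        return d


@dataclass
class RatRecord:
    rat: str
    condition: str
    hr_traces: dict  # day -> HeartRateTrace
    hormone_samples: list  # rows: dicts with hormone, day, pre/post conc + od
    freezing: FreezingSeries
    section: SectionMask
    truth: dict


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_heart_rate(cfg: HeartRateModel, rng: np.random.Generator, rat: str,
                   condition: str, day: int) -> HeartRateTrace:
    """Baseline + stimulation-locked logistic rise (active rats), noise,
    and dropout gaps.  The day-4 rise is scaled by the blunting factor."""
    dt = 1.0 / cfg.sample_rate_hz
    times = np.arange(0.0, cfg.duration_s + 0.5 * dt, dt)
    base = rng.normal(cfg.baseline_bpm_mean, cfg.baseline_bpm_sd)
    mean_rise = cfg.stim_rise_fraction if condition == "active" else 0.0
    if day >= 4:
        mean_rise *= cfg.day4_blunting
    # per-rat spread of the stimulation response in both conditions
    rise_frac = rng.normal(mean_rise, cfg.rise_sd)
    lo, hi = DEFAULT_STIM_WINDOW
    shape = _logistic((times - (lo + 10.0)) / 5.0) * np.where(
        times <= hi, 1.0, np.exp(-(times - hi) / 30.0)
    )
    mean = base * (1.0 + rise_frac * shape)
    bpm = mean + rng.normal(0.0, cfg.noise_sd_bpm, size=times.size)
    bpm = np.maximum(bpm, 1.0)
    truth_bpm = bpm.copy()
    if cfg.gap_rate > 0:
        drop = rng.random(times.size) < cfg.gap_rate
        # keep the edge windows observable so imputation preconditions hold
        drop[:11] = False
        drop[-11:] = False
        bpm = bpm.copy()
        bpm[drop] = np.nan
    trace = HeartRateTrace(times=times, bpm=bpm, stim_window=(lo, hi),
                           rat=rat, day=day, condition=condition)
    trace_truth = {"baseline_bpm": float(base), "rise_fraction": float(rise_frac),
                   "full_bpm": truth_bpm}
    return trace, trace_truth


def gen_hormones(cfg: HormoneModel, rng: np.random.Generator, rat: str,
                 condition: str) -> tuple[list, dict]:
    """Log-normal baselines; post = pre x condition effect x noise.
    Concentrations are also pushed through the latent plate curves to
    give optical densities."""
    rows, truth = [], {}
    for hormone, mlog in cfg.baseline_log_mean.items():
        a, b, c, d = cfg.plate_curves[hormone]
        effect = cfg.post_pre_effect[condition]
        truth[hormone] = {"effect": effect, "days": []}
        for day in range(1, cfg.n_days + 1):
            pre = float(np.exp(rng.normal(mlog, cfg.baseline_log_sd)))
            post = float(pre * effect * np.exp(rng.normal(0.0, cfg.ratio_log_sd)))
            row = {"rat": rat, "condition": condition, "hormone": hormone, "day": day,
                   "pre_conc": pre, "post_conc": post,
                   "pre_od": float(forward_4pl(pre, a, b, c, d) + rng.normal(0, cfg.od_noise_sd)),
                   "post_od": float(forward_4pl(post, a, b, c, d) + rng.normal(0, cfg.od_noise_sd)),
                   "plate": f"{hormone}_plate"}
            rows.append(row)
            truth[hormone]["days"].append({"pre": pre, "post": post})
    return rows, truth


def freezing_trial_means(cfg: FreezingModel, condition: str, acquirer: bool) -> dict:
    """Latent per-trial mean freezing curves for each phase."""
    means = {}
    means["habituation"] = np.full(TRIALS_PER_PHASE["habituation"], cfg.habituation_level)
    tc = np.arange(1, TRIALS_PER_PHASE["conditioning"] + 1)
    if acquirer:
        means["conditioning"] = cfg.asymptote * (1.0 - np.exp(-cfg.acquisition_rate * tc))
        f_start = float(means["conditioning"][-1])
        lam = cfg.extinction_decay * (cfg.treatment_decay_modifier if condition == "active" else 1.0)
        te = np.arange(1, TRIALS_PER_PHASE["extinction"] + 1)
        means["extinction"] = cfg.extinction_floor + (f_start - cfg.extinction_floor) * np.exp(-lam * te)
        means["recall"] = np.full(TRIALS_PER_PHASE["recall"], float(means["extinction"][-1]))
    else:
        means["conditioning"] = np.full(TRIALS_PER_PHASE["conditioning"], cfg.habituation_level)
        means["extinction"] = np.full(TRIALS_PER_PHASE["extinction"], cfg.habituation_level)
        means["recall"] = np.full(TRIALS_PER_PHASE["recall"], cfg.habituation_level)
    return means


def gen_freezing(cfg: FreezingModel, rng: np.random.Generator, rat: str,
                 condition: str) -> tuple[FreezingSeries, dict]:
    """Beta-distributed freezing around latent acquisition/decay curves.
    Non-acquirers stay flat at the habituation level."""
    acquirer = bool(rng.random() >= cfg.non_acquirer_fraction)
    means = freezing_trial_means(cfg, condition, acquirer)
    phases = {}
    for name in PHASES:
        mu = np.clip(means[name], 1e-3, 1.0 - 1e-3)
        alpha = mu * cfg.precision
        beta = (1.0 - mu) * cfg.precision
        phases[name] = rng.beta(alpha, beta)
    series = FreezingSeries(rat=rat, condition=condition, phases=phases)
    truth = {"acquirer": acquirer,
             "trial_means": {k: v.tolist() for k, v in means.items()}}
    return series, truth


def gen_section_masks(cfg: HistologyModel, rng: np.random.Generator) -> tuple[SectionMask, dict]:
    """Elliptical tissue mask with particle blobs placed by zone
    probabilities (normalized elliptical radius sampled within the
    target band)."""
    h, w = cfg.image_shape
    a, b = cfg.semi_axes_px
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = h / 2.0, w / 2.0
    r = np.sqrt(((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2)
    tissue = r <= 1.0
    particles = np.zeros_like(tissue)
    zones = list(cfg.zone_probs)
    probs = np.array([cfg.zone_probs[z] for z in zones], dtype=float)
    probs = probs / probs.sum()
    edges = {"medulla": (0.0, cfg.bands[0]), "ZR": (cfg.bands[0], cfg.bands[1]),
             "ZF": (cfg.bands[1], cfg.bands[2]), "ZG": (cfg.bands[2], 1.0)}
    placed = []
    for _ in range(cfg.n_blobs):
        zone = zones[int(rng.choice(len(zones), p=probs))]
        lo, hi = edges[zone]
        # sample a radius well inside the band so the blob stays in-zone
        pad = cfg.blob_radius_px / min(a, b)
        rt = rng.uniform(lo + pad, max(hi - pad, lo + pad + 1e-6))
        th = rng.uniform(0.0, 2.0 * np.pi)
        py = cy + rt * a * np.cos(th)
        px = cx + rt * b * np.sin(th)
        blob = (rr - py) ** 2 + (cc - px) ** 2 <= cfg.blob_radius_px**2
        particles |= blob & tissue
        placed.append({"zone": zone, "center": [float(py), float(px)],
                       "radius_px": cfg.blob_radius_px})
    mask = SectionMask(tissue=tissue, particles=particles)
    return mask, {"blobs": placed, "semi_axes_px": [a, b], "bands": list(cfg.bands)}


def gen_calorimetry(cfg: CalorimetryModel, rng: np.random.Generator) -> tuple[CalorimetryTrace, dict]:
    """Linear heating at the slope implied by the configured SLP, with
    Gaussian temperature noise and a flat pre-field baseline."""
    dt = 1.0 / cfg.sample_rate_hz
    times = np.arange(0.0, cfg.duration_s + 0.5 * dt, dt)
    iron_mass_g = cfg.iron_mass_kg * 1e3
    slope = cfg.true_slp * iron_mass_g / (cfg.solution_heat_capacity * cfg.solution_mass_kg)
    temp = cfg.start_temp_c + np.where(times >= cfg.field_on_s,
                                       slope * (times - cfg.field_on_s), 0.0)
    temp = temp + rng.normal(0.0, cfg.noise_sd_k, size=times.size)
    trace = CalorimetryTrace(times=times, temperatures=temp,
                             field_on_time=cfg.field_on_s,
                             solution_mass_kg=cfg.solution_mass_kg,
                             iron_mass_kg=cfg.iron_mass_kg,
                             solution_heat_capacity=cfg.solution_heat_capacity,
                             condition=CALORIMETER_CONDITION)
    return trace, {"true_slp": cfg.true_slp, "true_slope": float(slope)}


def gen_cohort(config: CohortConfig, seed: int | None = None) -> list[RatRecord]:
    """Generate the full cohort (both conditions) deterministically."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for condition in ("control", "active"):
        for _ in range(config.n_per_condition):
            idx += 1
            rat = f"rat{idx:02d}"
            hr, hr_truth = {}, {}
            for day in (1, 2, 4):
                trace, t = gen_heart_rate(config.heart_rate, rng, rat, condition, day)
                hr[day] = trace
                hr_truth[day] = {k: v for k, v in t.items() if k != "full_bpm"}
            hormone_rows, hormone_truth = gen_hormones(config.hormones, rng, rat, condition)
            freezing, freezing_truth = gen_freezing(config.freezing, rng, rat, condition)
            section, hist_truth = gen_section_masks(config.histology, rng)
            records.append(RatRecord(
                rat=rat, condition=condition, hr_traces=hr,
                hormone_samples=hormone_rows, freezing=freezing, section=section,
                truth={"heart_rate": hr_truth, "hormones": hormone_truth,
                       "freezing": freezing_truth, "histology": hist_truth},
            ))
    return records


def write_cohort(records: list[RatRecord], config: CohortConfig, out_dir) -> Path:
    """Write the CSV/PNG layouts the analyze-* commands consume, plus a
    manifest and the ground-truth JSON."""
    from PIL import Image

    out = Path(out_dir)
    (out / "heart_rate").mkdir(parents=True, exist_ok=True)
    (out / "histology").mkdir(exist_ok=True)
    hr_manifest = []
    hormone_rows = []
    freezing_rows = []
    truth = {}
    for rec in records:
        truth[rec.rat] = rec.truth
        for day, trace in rec.hr_traces.items():
            fname = f"heart_rate/{rec.rat}_day{day}.csv"
            pd.DataFrame({"time_s": trace.times, "bpm": trace.bpm}).to_csv(
                out / fname, index=False)
            hr_manifest.append({"rat": rec.rat, "day": day,
                                "condition": rec.condition, "file": fname})
        hormone_rows.extend(rec.hormone_samples)
        for phase in PHASES:
            for j, v in enumerate(rec.freezing.phases[phase], start=1):
                freezing_rows.append({"rat": rec.rat, "condition": rec.condition,
                                      "phase": phase, "trial": j,
                                      "percent_freezing": 100.0 * v})
        for kind, arr in (("tissue", rec.section.tissue), ("particles", rec.section.particles)):
            img = Image.fromarray((arr * 255).astype(np.uint8))
            img.save(out / "histology" / f"{rec.rat}_{kind}.png")
    pd.DataFrame(hr_manifest).to_csv(out / "hr_manifest.csv", index=False)
    pd.DataFrame(hormone_rows).to_csv(out / "hormone_samples.csv", index=False)
    pd.DataFrame(freezing_rows).to_csv(out / "freezing.csv", index=False)

    # plate standards per hormone from the latent curves
    std_rows = []
    for hormone, (a, b, c, d) in config.hormones.plate_curves.items():
        concs = c * np.array([0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
        for conc in concs:
            std_rows.append({"plate": f"{hormone}_plate", "hormone": hormone,
                             "type": "standard", "known_conc": float(conc),
                             "od": float(forward_4pl(conc, a, b, c, d))})
    pd.DataFrame(std_rows).to_csv(out / "plate_standards.csv", index=False)

    with open(out / "ground_truth.json", "w") as f:
        json.dump({"config": config.to_dict(), "rats": truth}, f, indent=1, default=str)
    return out
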