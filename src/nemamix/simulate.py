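"""Stage-structured stochastic simulator of C. elegans populations under
single-metal and mixture exposure, with the transfer/dilution protocol of
a liquid-medium population assay.

The simulator advances hourly. Individuals are grouped into cohorts by
stage (egg, L1-L4, adult) and age-in-stage; each hour every cohort

1. survives with probability exp(-h * m_s) where h is the per-hour
   exposure hazard and m_s a stage sensitivity multiplier,
2. lays eggs if it is a fertile adult (founders lay from the start of the
   assay; offspring adults from a configurable adult age onwards, for a
   4-day fertile window),
3. ages by one hour, graduating to the next stage when the (dose-delayed)
   stage duration is reached, and
4. is thinned binomially with probability 1/divisor at transfer events.

The per-hour hazard is derived from 24 h lethal-concentration curves:
a concentration whose 24 h mortality is y% corresponds to the constant
hazard h = -ln(1 - y/100) / 24 h. Mixtures combine hazards under
independent action (hazards add: survival probabilities multiply),
concentration addition (the CA effect of the instantaneous mixture is
converted to a single hazard), or a phenomenological protective Zn-on-Cd
mode in which Zn scales Cd's effective concentration by a U-shaped factor
g(c_Zn): protection deepens as Zn rises, is near-complete around the
protection-optimal Zn concentration, and is lost again above a Zn
overload threshold (about 1 mM), while Zn's own hazard always acts.

Sub-lethal toxicity uses the same dose scale: with s = 1 - exp(-24 h)
the 24 h kill fraction of the exposure, stage durations are multiplied by
(1 + delay * s) and per-adult fecundity by max(0, 1 - reduction * s).

The ~10 founder adults are tracked separately from their offspring so
that founder-cohort mortality (the quantity scored in short mixture
assays) is always available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import MG_PER_L, Concentration, LogLogisticCurve, effect_at
from .endpoints import DilutionSchedule, MortalityRecord
from .mixtures import MixtureExposure, predict_ca

__all__ = [
    "STAGES",
    "LARVAL_STAGES",
    "StageParams",
    "ProtectiveZnCd",
    "HazardModel",
    "SimConfig",
    "SimOutput",
    "hazard_from_lc",
    "combined_hazard",
    "simulate",
    "generate_experiment",
]

STAGES = ("egg", "L1", "L2", "L3", "L4", "adult")
LARVAL_STAGES = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class StageParams:
    """Stage durations (h at 20 C), body lengths (mm) and hazard multipliers.

    Default lengths are anchored to ~0.37 mm at the first molt, ~1.06 mm
    at the start of egg laying and 1-1.5 mm adults; default durations give
    a ~3-day egg-to-adult time, within the 3-4 day generation time of the
    species. Larvae are more metal-sensitive than adults; eggs are
    shielded by the egg shell.
    """

    durations_h: Mapping[str, float] = field(
        default_factory=lambda: {"egg": 16.0, "L1": 16.0, "L2": 12.0, "L3": 12.0, "L4": 16.0}
    )
    lengths_mm: Mapping[str, float] = field(
        default_factory=lambda: {
            "L1": 0.25,
            "L2": 0.37,
            "L3": 0.55,
            "L4": 0.80,
            "adult": 1.20,
        }
    )
    sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {
            "egg": 0.2,
            "L1": 2.5,
            "L2": 2.5,
            "L3": 2.5,
            "L4": 2.5,
            "adult": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for stage in ("egg", *LARVAL_STAGES):
            if not (self.durations_h.get(stage, 0) > 0):
                raise ValueError(f"duration for stage {stage!r} must be positive")
        lengths = [self.lengths_mm[s] for s in (*LARVAL_STAGES, "adult")]
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("body lengths must increase with stage")


def hazard_from_lc(
    curve: LogLogisticCurve, c: Concentration, window_h: float = 24.0
) -> float:
    """Constant per-hour hazard reproducing the curve's mortality at ``c``.

    h = -ln(1 - y(c)/100) / window, so a cohort held for the window dies
    at exactly the dose-response fraction in expectation.
    """
    y = effect_at(curve, c)
    if y >= 100.0:
        raise ValueError("mortality fraction must be below 100% for a finite hazard")
    return -math.log1p(-y / 100.0) / window_h


@dataclass(frozen=True)
class ProtectiveZnCd:
    """U-shaped Zn-on-Cd protection factor g(c_Zn) applied to Cd's
    effective concentration.

    g falls from 1 toward ``g_min`` with a Hill-type decline (half
    protection at ``half_mg_l``), stays near ``g_min`` through the
    protection-optimal range, and rises back toward 1 above the Zn
    overload concentration (default 1 mM Zn = 65.38 mg/L) with a sharp
    Hill recovery — the phenomenological analogue of a saturable Zn
    detoxification capacity.
    """

    g_min: float = 0.02
    half_mg_l: float = 0.45
    hill: float = 2.5
    overload_mg_l: float = 65.38
    overload_hill: float = 6.0

    def factor(self, c_zn_mg_l: float) -> float:
        if c_zn_mg_l <= 0:
            return 1.0
        u = (c_zn_mg_l / self.half_mg_l) ** self.hill
        v = (c_zn_mg_l / self.overload_mg_l) ** self.overload_hill
        depth = (1.0 - self.g_min) * (u / (1.0 + u)) / (1.0 + v)
        return 1.0 - depth


_MODES = ("IA", "CA", "protective_zn_cd")


@dataclass(frozen=True)
class HazardModel:
    """Per-compound 24 h mortality curves plus a hazard-combination rule."""

    curves: Mapping[str, LogLogisticCurve]
    mode: str = "IA"
    protective: ProtectiveZnCd = field(default_factory=ProtectiveZnCd)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown combination mode {self.mode!r}; expected {_MODES}")

    def effective_concentrations(
        self, exposure: Mapping[str, float]
    ) -> dict[str, float]:
        """Exposure in mg/L after the protective Zn-on-Cd adjustment."""
        concs = {k: float(v) for k, v in exposure.items() if v > 0}
        if self.mode == "protective_zn_cd" and "Cd" in concs:
            concs["Cd"] = concs["Cd"] * self.protective.factor(concs.get("Zn", 0.0))
        return concs

    def hazard(self, exposure: Mapping[str, float]) -> float:
        """Combined per-hour hazard for an exposure (mg/L per compound)."""
        return combined_hazard(self, exposure)


def combined_hazard(hm: HazardModel, exposure: Mapping[str, float]) -> float:
    """Per-hour hazard of an exposure under the model's combination rule.

    IA adds single-compound hazards (independent competing risks, whose
    24 h survival product is exactly the IA prediction); CA converts the
    CA-predicted 24 h mixture effect to one hazard; the protective mode
    is IA on Zn-adjusted effective concentrations.
    """
    concs = hm.effective_concentrations(exposure)
    unknown = set(concs) - set(hm.curves)
    if unknown:
        raise KeyError(f"no dose-response curve for compound(s) {sorted(unknown)}")
    if not concs:
        return 0.0
    if hm.mode == "CA":
        mix = MixtureExposure.of(
            *(
                (hm.curves[name], Concentration(c, MG_PER_L))
                for name, c in concs.items()
            )
        )
        y = predict_ca(mix)
        return -math.log1p(-y / 100.0) / 24.0
    # IA and protective: hazards add
    return sum(
        hazard_from_lc(hm.curves[name], Concentration(c, MG_PER_L))
        for name, c in concs.items()
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated well."""

    hazards: HazardModel
    treatment: str = "control"
    replicate: int | str = 1
    exposure: Mapping[str, float] = field(default_factory=dict)  # mg/L
    n_start_adults: int = 10
    duration_days: float = 10.0
    schedule: DilutionSchedule = field(default_factory=DilutionSchedule)
    fecundity: float = 50.0  # eggs per adult per day in the fertile window
    fertile_window_days: float = 4.0
    fertile_onset_h: float = 24.0  # offspring adult age at first egg
    adult_lifespan_days: float = 14.0
    stages: StageParams = field(default_factory=StageParams)
    development_delay: float = 5.0  # duration multiplier coefficient
    fecundity_reduction: float = 4.5  # brood reduction coefficient
    length_sample_days: tuple[float, ...] = ()
    length_sample_size: int = 20
    length_noise_sd: float = 0.06
    mortality_record_hours: tuple[float, ...] = (0.0, 24.0, 48.0)
    seed: int = 0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.n_start_adults < 0:
            raise ValueError("n_start_adults must be >= 0")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")
        for name, value in (
            ("fecundity", self.fecundity),
            ("fertile_window_days", self.fertile_window_days),
            ("adult_lifespan_days", self.adult_lifespan_days),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimOutput:
    """Simulator observables plus the ground-truth internal state."""

    config: SimConfig
    hourly: pd.DataFrame  # time_h, per-stage totals, founders, well_total
    counts: pd.DataFrame  # day, counted_n (in-well, eggs excluded)
    lengths: pd.DataFrame  # day, length_mm samples of the most developed
    mortality: list[MortalityRecord]
    truth: dict


def _thin(values: np.ndarray | float, p: float, rng, deterministic: bool):
    if deterministic:
        return values * p
    if np.isscalar(values):
        return rng.binomial(int(values), p)
    return rng.binomial(values.astype(np.int64), p)


def simulate(config: SimConfig) -> SimOutput:
    """Run one well forward; seeded and reproducible.

    ``deterministic`` propagates expected values (real-valued cohorts)
    instead of sampling, which is useful as a closed-form oracle.
    """
    rng = np.random.default_rng(config.seed)
    det = config.deterministic
    stages = config.stages

    h0 = config.hazards.hazard(config.exposure)
    s24 = 1.0 - math.exp(-24.0 * h0)  # 24 h kill fraction of the exposure
    delay = 1.0 + config.development_delay * s24
    fecundity = config.fecundity * max(0.0, 1.0 - config.fecundity_reduction * s24)
    rate_h = fecundity / 24.0

    durations = {
        stage: max(1, int(round(stages.durations_h[stage] * delay)))
        for stage in ("egg", *LARVAL_STAGES)
    }
    lifespan_h = max(1, int(round(config.adult_lifespan_days * 24.0)))
    survival = {
        stage: math.exp(-h0 * stages.sensitivity[stage]) for stage in STAGES
    }

    dtype = float if det else np.int64
    cohorts = {
        stage: np.zeros(durations[stage], dtype=dtype)
        for stage in ("egg", *LARVAL_STAGES)
    }
    adults = np.zeros(lifespan_h, dtype=dtype)
    founders = float(config.n_start_adults) if det else int(config.n_start_adults)

    fertile_window_h = config.fertile_window_days * 24.0
    events = {float(t): int(d) for t, d in config.schedule.events}
    duration_h = int(round(config.duration_days * 24.0))

    adult_ages = np.arange(lifespan_h)
    fertile_mask = (adult_ages >= config.fertile_onset_h) & (
        adult_ages < config.fertile_onset_h + fertile_window_h
    )

    def well_total() -> float:
        larvae = sum(float(cohorts[s].sum()) for s in LARVAL_STAGES)
        return larvae + float(adults.sum()) + float(founders)

    hourly_rows = []
    counts_rows = []
    length_rows = []
    mortality_records: list[MortalityRecord] = []
    sample_days = set(float(d) for d in config.length_sample_days)

    def record(t_h: int) -> None:
        row = {"time_h": float(t_h)}
        for stage in ("egg", *LARVAL_STAGES):
            row[stage] = float(cohorts[stage].sum())
        row["adult"] = float(adults.sum()) + float(founders)
        row["founders_alive"] = float(founders)
        row["well_total"] = well_total()
        hourly_rows.append(row)
        if t_h % 24 == 0:
            day = t_h / 24.0
            counted = well_total()
            counts_rows.append(
                {"day": day, "counted_n": counted if det else int(counted)}
            )
            if day in sample_days:
                for length in _sample_lengths(
                    cohorts, adults, founders, stages, config, rng
                ):
                    length_rows.append({"day": day, "length_mm": length})
        if float(t_h) in config.mortality_record_hours and not det:
            mortality_records.append(
                MortalityRecord(
                    treatment=config.treatment,
                    replicate=config.replicate,
                    time_h=float(t_h),
                    n_start=config.n_start_adults,
                    n_alive=int(founders),
                )
            )

    record(0)
    for t in range(1, duration_h + 1):
        # 1. mortality
        for stage in ("egg", *LARVAL_STAGES):
            cohorts[stage] = _thin(cohorts[stage], survival[stage], rng, det)
        adults = _thin(adults, survival["adult"], rng, det)
        founders = _thin(founders, survival["adult"], rng, det)
        # 2. egg laying by surviving fertile adults
        n_fertile = float(adults[fertile_mask].sum())
        if t <= fertile_window_h:
            n_fertile += float(founders)
        expected_eggs = rate_h * n_fertile
        new_eggs = expected_eggs if det else rng.poisson(expected_eggs)
        # 3. aging and graduation
        hatched = cohorts["egg"][-1]
        cohorts["egg"] = np.concatenate(([new_eggs], cohorts["egg"][:-1]))
        inflow = hatched
        for stage in LARVAL_STAGES:
            graduated = cohorts[stage][-1]
            cohorts[stage] = np.concatenate(([inflow], cohorts[stage][:-1]))
            inflow = graduated
        adults = np.concatenate(([inflow], adults[:-1]))  # beyond lifespan: death
        if not det:
            cohorts = {k: v.astype(np.int64) for k, v in cohorts.items()}
            adults = adults.astype(np.int64)
        # 4. transfer / split event
        if float(t) in events:
            p = 1.0 / events[float(t)]
            for stage in ("egg", *LARVAL_STAGES):
                cohorts[stage] = _thin(cohorts[stage], p, rng, det)
            adults = _thin(adults, p, rng, det)
            founders = _thin(founders, p, rng, det)
        record(t)

    truth = {
        "treatment": config.treatment,
        "replicate": config.replicate,
        "exposure_mg_per_L": dict(config.exposure),
        "hazard_per_h": h0,
        "kill_fraction_24h": s24,
        "stage_durations_h": durations,
        "fecundity_effective": fecundity,
        "seed": config.seed,
        "per_day_well_total": {
            str(row["day"]): float(row["counted_n"]) for row in counts_rows
        },
    }
    return SimOutput(
        config=config,
        hourly=pd.DataFrame(hourly_rows),
        counts=pd.DataFrame(counts_rows),
        lengths=pd.DataFrame(length_rows, columns=["day", "length_mm"]),
        mortality=mortality_records,
        truth=truth,
    )


def _sample_lengths(
    cohorts: Mapping[str, np.ndarray],
    adults: np.ndarray,
    founders,
    stages: StageParams,
    config: SimConfig,
    rng,
) -> list[float]:
    """Body lengths of the most developed individuals present.

    The measurement protocol scores the post-larval-looking worms in view,
    so samples are drawn from the most advanced stages first (adults, then
    L4 down to L1); eggs are never measured. Gaussian measurement noise is
    added (none in deterministic mode), truncated to plausible lengths.
    """
    pool = [
        ("adult", float(adults.sum()) + float(founders)),
        ("L4", float(cohorts["L4"].sum())),
        ("L3", float(cohorts["L3"].sum())),
        ("L2", float(cohorts["L2"].sum())),
        ("L1", float(cohorts["L1"].sum())),
    ]
    lengths: list[float] = []
    remaining = config.length_sample_size
    for stage, count in pool:
        take = int(min(remaining, count))
        base = stages.lengths_mm[stage]
        for _ in range(take):
            if config.deterministic:
                lengths.append(base)
            else:
                lengths.append(
                    float(np.clip(base + rng.normal(0.0, config.length_noise_sd), 0.05, 1.99))
                )
        remaining -= take
        if remaining <= 0:
            break
    return lengths


def generate_experiment(
    configs: Sequence[SimConfig], out_dir: str | Path
) -> dict[str, Path]:
    """Run a set of wells and emit the four analysis CSV tables.

    Writes counts.csv, schedule.csv, lengths.csv and mortality.csv in the
    schemas of the endpoint pipeline, plus ground_truth.json holding the
    simulator's internal state for testing. Deterministic for fixed
    per-config seeds: re-running yields byte-identical files.
    """
    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_rows = []
    length_rows = []
    mortality: list[MortalityRecord] = []
    schedules: dict[str, DilutionSchedule] = {}
    truths = []
    for config in configs:
        result = simulate(config)
        schedules[config.treatment] = config.schedule
        for row in result.counts.itertuples():
            counts_rows.append(
                {
                    "treatment": config.treatment,
                    "replicate": config.replicate,
                    "day": row.day,
                    "counted_n": int(row.counted_n),
                }
            )
        for row in result.lengths.itertuples():
            length_rows.append(
                {
                    "treatment": config.treatment,
                    "replicate": config.replicate,
                    "day": row.day,
                    "length_mm": round(float(row.length_mm), 4),
                }
            )
        mortality.extend(result.mortality)
        truths.append(result.truth)

    paths = {
        "counts": out / "counts.csv",
        "schedule": out / "schedule.csv",
        "lengths": out / "lengths.csv",
        "mortality": out / "mortality.csv",
        "truth": out / "ground_truth.json",
    }
    nio.write_counts(
        pd.DataFrame(counts_rows, columns=["treatment", "replicate", "day", "counted_n"]),
        paths["counts"],
    )
    nio.write_schedules(schedules, paths["schedule"])
    pd.DataFrame(
        length_rows, columns=["treatment", "replicate", "day", "length_mm"]
    ).to_csv(paths["lengths"], index=False)
    nio.write_mortality(mortality, paths["mortality"])
    with open(paths["truth"], "w") as fh:
        json.dump(truths, fh, indent=1, sort_keys=True)
    return paths
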