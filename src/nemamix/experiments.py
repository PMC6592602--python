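"""Ready-made experiment scenarios built on the simulator.

Two designs mirror the population study: the main multi-metal experiment
(8 treatments x 3 replicates x 10-12 days with 36 h transfer splits) and
the ZnCd series (five Zn levels with and without an LC20 concentration of
Cd, 6 replicates, 48 h, founder mortality scored at 24 h and 48 h).

Also provided: a plain mortality assay (one cohort, no reproduction) used
for dose-response work, and a parameter-recovery study that simulates
24 h mortalities at the reference Zn doses and refits the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import (
    MG_PER_L,
    Concentration,
    FitResult,
    LogLogisticCurve,
    curve_from_lc_table,
    fit_loglogistic,
    load_reference_lc_table,
)
from .endpoints import DilutionSchedule, control_lc20_schedule, standard_schedule
from .mixtures import (
    InteractionCall,
    MixtureExposure,
    MixturePrediction,
    classify_interaction,
    predict_ca,
    predict_ia,
    ratio_profile,
)
from .simulate import HazardModel, SimConfig, simulate

__all__ = [
    "reference_curves",
    "default_hazard_model",
    "extend_effect",
    "main_experiment_configs",
    "zncd_series",
    "ZnCdSeriesResult",
    "mortality_assay",
    "recovery_study",
    "RecoveryStudyResult",
]

ZN_LEVELS = (2.0, 5.0, 20.0, 40.0, 60.0)


def reference_curves() -> dict[str, LogLogisticCurve]:
    """Log-logistic curves fitted to the packaged 24 h LC table.

    Zn uses the least-squares fit over its five printed LC levels; Cu and
    Cd are exactly identified from their LC5/LC20 pairs.
    """
    tables = load_reference_lc_table()
    return {name: curve_from_lc_table(table) for name, table in tables.items()}


def default_hazard_model(mode: str = "IA") -> HazardModel:
    return HazardModel(curves=reference_curves(), mode=mode)


def extend_effect(y_percent: float, hours: float, window_h: float = 24.0) -> float:
    """Extend a window-referenced kill fraction to another exposure time
    assuming a constant hazard: survival raises to the power hours/window."""
    frac = hours / window_h
    return 100.0 * (1.0 - (1.0 - y_percent / 100.0) ** frac)


# ---------------------------------------------------------------------------
# main multi-metal population experiment


def main_experiment_configs(
    seed: int,
    level: float = 20.0,
    n_replicates: int = 3,
    mode: str = "protective_zn_cd",
) -> list[SimConfig]:
    """The 8-treatment design (control, Zn, Cu, Cd, ZnCu, ZnCd, CuCd,
    ZnCuCd) at a common LC level, with the routine 36 h split schedule.

    LC20 exposures run 10 days (with the extra-dilution control
    schedule); LC5 exposures run 12 days with the day-6 deviations of the
    protocol (factor 8 for control/Zn/Cu, factor 4 otherwise).
    """
    tables = load_reference_lc_table()
    hazards = default_hazard_model(mode)
    if level == 20.0:
        duration_days, sample_days = 10.0, (0.0, 5.0, 10.0)
    elif level == 5.0:
        duration_days, sample_days = 12.0, (0.0, 5.0, 10.0, 12.0)
    else:
        raise ValueError("the main design is defined at LC level 5 or 20")
    duration_h = duration_days * 24.0

    def dose(compound: str) -> float:
        return tables[compound].concentration(level).value

    treatments = {
        "control": {},
        "Zn": {"Zn": dose("Zn")},
        "Cu": {"Cu": dose("Cu")},
        "Cd": {"Cd": dose("Cd")},
        "ZnCu": {"Zn": dose("Zn"), "Cu": dose("Cu")},
        "ZnCd": {"Zn": dose("Zn"), "Cd": dose("Cd")},
        "CuCd": {"Cu": dose("Cu"), "Cd": dose("Cd")},
        "ZnCuCd": {"Zn": dose("Zn"), "Cu": dose("Cu"), "Cd": dose("Cd")},
    }

    def schedule_for(name: str) -> DilutionSchedule:
        if level == 20.0:
            if name == "control":
                return control_lc20_schedule()
            return standard_schedule(duration_h)
        # LC5: day-6 split is a factor 8 for control/Zn/Cu, 4 otherwise
        day6_divisor = 8 if name in ("control", "Zn", "Cu") else 4
        events = [
            (t, day6_divisor if t == 144.0 else d)
            for t, d in standard_schedule(duration_h).events
        ]
        return DilutionSchedule(tuple(events))

    configs = []
    for i, (name, exposure) in enumerate(treatments.items()):
        for rep in range(1, n_replicates + 1):
            configs.append(
                SimConfig(
                    hazards=hazards,
                    treatment=name,
                    replicate=rep,
                    exposure=exposure,
                    duration_days=duration_days,
                    schedule=schedule_for(name),
                    length_sample_days=sample_days,
                    seed=int(np.random.SeedSequence([seed, i, rep]).generate_state(1)[0] % 2**31),
                )
            )
    return configs


# ---------------------------------------------------------------------------
# ZnCd mixture series


@dataclass
class ZnCdSeriesResult:
    """Observed, predicted and classified outcomes of the ZnCd series."""

    observed: pd.DataFrame  # zn_level, treatment, time_h, replicate, mortality
    predictions: pd.DataFrame  # zn_level, time_h, y_ca, y_ia
    expected: pd.DataFrame  # deterministic mixture/single expectations
    calls: dict[tuple[float, float], InteractionCall] = field(default_factory=dict)

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for (zn_level, time_h), call in sorted(self.calls.items()):
            rows.append(
                {
                    "zn_level": zn_level,
                    "time_h": time_h,
                    "label": call.label,
                    "p_vs_ca": call.p_vs_ca,
                    "p_vs_ia": call.p_vs_ia,
                    "direction_vs_ca": call.direction_vs_ca,
                    "direction_vs_ia": call.direction_vs_ia,
                }
            )
        return pd.DataFrame(rows)

    def mortality_ratios(self, time_h: float = 24.0) -> pd.Series:
        """Observed mean mixture mortality relative to the Cd-only mean."""
        obs = self.observed[self.observed["time_h"] == time_h]
        cd_only = obs[obs["treatment"] == "Cd"]["mortality"].mean()
        mix = (
            obs[obs["treatment"].str.startswith("Zn") & obs["treatment"].str.contains("Cd")]
            .groupby("zn_level")["mortality"]
            .mean()
        )
        return ratio_profile(mix, cd_only)

    def expected_ratios(self, time_h: float = 24.0) -> pd.Series:
        """Deterministic mixture/Cd-only mortality ratio across Zn levels."""
        exp = self.expected[self.expected["time_h"] == time_h]
        cd_only = float(exp["expected_cd_only"].iloc[0])
        return ratio_profile(
            exp.set_index("zn_level")["expected_mixture"], cd_only
        )


def zncd_series(
    seed: int,
    n_replicates: int = 6,
    n_start_adults: int = 10,
    mode: str = "protective_zn_cd",
    alpha: float = 0.05,
) -> ZnCdSeriesResult:
    """Run and classify the ZnCd mixture series.

    Five Zn levels (LC2-LC60) each with and without Cd at its LC20, plus a
    Cd-only arm; 48 h, no transfers; founder mortality scored at 24 h and
    48 h and compared against the CA and IA predictions per time point.
    48 h predictions extend the 24 h model effect under the constant-hazard
    assumption.
    """
    tables = load_reference_lc_table()
    curves = reference_curves()
    hazards = HazardModel(curves=curves, mode=mode)
    cd_dose = tables["Cd"].concentration(20.0).value
    zn_doses = {lvl: tables["Zn"].concentration(lvl).value for lvl in ZN_LEVELS}

    treatments: dict[str, dict[str, float]] = {"Cd": {"Cd": cd_dose}}
    for lvl, zn in zn_doses.items():
        treatments[f"Zn{lvl:g}"] = {"Zn": zn}
        treatments[f"Zn{lvl:g}Cd"] = {"Zn": zn, "Cd": cd_dose}

    obs_rows = []
    expected_rows = []
    for i, (name, exposure) in enumerate(treatments.items()):
        for rep in range(1, n_replicates + 1):
            config = SimConfig(
                hazards=hazards,
                treatment=name,
                replicate=rep,
                exposure=exposure,
                n_start_adults=n_start_adults,
                duration_days=2.0,
                mortality_record_hours=(0.0, 24.0, 48.0),
                seed=int(
                    np.random.SeedSequence([seed, i, rep]).generate_state(1)[0] % 2**31
                ),
            )
            result = simulate(config)
            for rec in result.mortality:
                if rec.time_h == 0.0:
                    continue
                obs_rows.append(
                    {
                        "treatment": name,
                        "zn_level": _zn_level_of(name),
                        "time_h": rec.time_h,
                        "replicate": rep,
                        "mortality": 100.0 * (rec.n_start - rec.n_alive) / rec.n_start,
                    }
                )

    pred_rows = []
    calls: dict[tuple[float, float], InteractionCall] = {}
    observed = pd.DataFrame(obs_rows)
    for lvl, zn in zn_doses.items():
        mix = MixtureExposure.of(
            (curves["Zn"], Concentration(zn, MG_PER_L)),
            (curves["Cd"], Concentration(cd_dose, MG_PER_L)),
        )
        y_ca24, y_ia24 = predict_ca(mix), predict_ia(mix)
        h_mix = hazards.hazard({"Zn": zn, "Cd": cd_dose})
        h_zn = hazards.hazard({"Zn": zn})
        h_cd = hazards.hazard({"Cd": cd_dose})
        for time_h in (24.0, 48.0):
            y_ca = extend_effect(y_ca24, time_h)
            y_ia = extend_effect(y_ia24, time_h)
            pred_rows.append(
                {"zn_level": lvl, "time_h": time_h, "y_ca": y_ca, "y_ia": y_ia}
            )
            expected_rows.append(
                {
                    "zn_level": lvl,
                    "time_h": time_h,
                    "expected_mixture": 100.0 * (1.0 - math.exp(-h_mix * time_h)),
                    "expected_zn_only": 100.0 * (1.0 - math.exp(-h_zn * time_h)),
                    "expected_cd_only": 100.0 * (1.0 - math.exp(-h_cd * time_h)),
                    "y_ca": y_ca,
                    "y_ia": y_ia,
                }
            )
            mask = (
                (observed["treatment"] == f"Zn{lvl:g}Cd")
                & (observed["time_h"] == time_h)
            )
            calls[(lvl, time_h)] = classify_interaction(
                observed.loc[mask, "mortality"].to_numpy(),
                MixturePrediction(y_ca=y_ca, y_ia=y_ia),
                alpha=alpha,
            )

    return ZnCdSeriesResult(
        observed=observed,
        predictions=pd.DataFrame(pred_rows),
        expected=pd.DataFrame(expected_rows),
        calls=calls,
    )


def _zn_level_of(treatment: str) -> float | None:
    if not treatment.startswith("Zn"):
        return None
    core = treatment[2:].removesuffix("Cd")
    try:
        return float(core)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# dose-response utilities on top of the simulator


def mortality_assay(
    hazards: HazardModel,
    exposure: dict[str, float],
    n_animals: int,
    seed: int,
    hours: float = 24.0,
) -> float:
    """Observed percent mortality of one adult cohort (no reproduction)."""
    config = SimConfig(
        hazards=hazards,
        treatment="assay",
        exposure=exposure,
        n_start_adults=n_animals,
        duration_days=hours / 24.0,
        fecundity=0.0,
        mortality_record_hours=(hours,),
        seed=seed,
    )
    result = simulate(config)
    rec = result.mortality[-1]
    return 100.0 * (rec.n_start - rec.n_alive) / rec.n_start


@dataclass
class RecoveryStudyResult:
    """Refitting success across seeded replicates of a mortality assay."""

    fits: pd.DataFrame  # replicate, ec50, beta, ec50_rel_err, beta_rel_err, ok
    true_ec50: float
    true_beta: float

    @property
    def success_rate(self) -> float:
        return float(self.fits["ok"].mean())


def recovery_study(
    seed: int,
    n_replicates: int = 100,
    n_per_dose: int = 1000,
    ec50_tol: float = 0.10,
    beta_tol: float = 0.15,
) -> RecoveryStudyResult:
    """Simulate 24 h Zn mortalities at the five reference doses and refit.

    Each replicate draws binomial mortalities of ``n_per_dose`` animals
    per dose through the simulator's hazard construction, then refits the
    log-logistic curve by inverse-variance weighted least squares. Success
    means EC50 within ``ec50_tol`` and beta within ``beta_tol`` of the
    generating curve.
    """
    tables = load_reference_lc_table()
    curves = reference_curves()
    truth = curves["Zn"]
    hazards = HazardModel(curves={"Zn": truth}, mode="IA")
    doses = [tables["Zn"].concentration(lvl).value for lvl in ZN_LEVELS]

    rows = []
    for rep in range(n_replicates):
        points = []
        weights = []
        for j, dose in enumerate(doses):
            rep_seed = int(
                np.random.SeedSequence([seed, rep, j]).generate_state(1)[0] % 2**31
            )
            y = mortality_assay(
                hazards, {"Zn": dose}, n_animals=n_per_dose, seed=rep_seed
            )
            # keep effects inside (0, 100) and weights finite
            y = min(max(y, 100.0 * 0.5 / n_per_dose), 100.0 * (1 - 0.5 / n_per_dose))
            points.append((Concentration(dose, MG_PER_L), y))
            p_hat = y / 100.0
            # inverse of the binomial variance of y on the percent scale
            weights.append(n_per_dose / (100.0**2 * p_hat * (1.0 - p_hat)))
        fit: FitResult = fit_loglogistic(
            points, weights=weights, compound=truth.compound
        )
        ec50_err = abs(fit.curve.ec50.value - truth.ec50.value) / truth.ec50.value
        beta_err = abs(fit.curve.beta - truth.beta) / truth.beta
        rows.append(
            {
                "replicate": rep,
                "ec50": fit.curve.ec50.value,
                "beta": fit.curve.beta,
                "ec50_rel_err": ec50_err,
                "beta_rel_err": beta_err,
                "ok": (ec50_err <= ec50_tol) and (beta_err <= beta_tol),
            }
        )
    return RecoveryStudyResult(
        fits=pd.DataFrame(rows),
        true_ec50=truth.ec50.value,
        true_beta=truth.beta,
    )
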