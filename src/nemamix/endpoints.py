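"""Population-size, body-length and mortality endpoints with the
serial-dilution bookkeeping and group comparisons used around them.

Counted wells undergo timed transfer events that split the population
(usually in two) to keep counts tractable; the cumulative product of the
split divisors relates an in-well count to the whole-population scale.
The three population endpoints are (i) the trapezoid-rule area under the
(log) population-vs-time curve, (ii) the maximum population attained, and
(iii) the end-of-experiment population. Group comparisons follow standard
ecotoxicology practice: one-way ANOVA with Dunnett (vs control) and Tukey
(all-pairs) post hocs for the endpoint values, and Kruskal-Wallis with
Bonferroni-corrected pairwise rank-sum tests for mortality fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DilutionSchedule",
    "PopulationSeries",
    "EndpointSummary",
    "MortalityRecord",
    "EndpointError",
    "cumulative_dilution_factor",
    "reconstruct_population",
    "auc_population",
    "endpoint_summary",
    "endpoint_table",
    "percent_vs_control",
    "mortality_fraction",
    "anova_dunnett_tukey",
    "kruskal_bonferroni",
    "length_slopes",
    "slope_contrast",
    "standard_schedule",
    "control_lc20_schedule",
]


class EndpointError(ValueError):
    """Raised for endpoint computations on degenerate inputs."""


@dataclass(frozen=True)
class DilutionSchedule:
    """Ordered transfer events: (time in hours since start, split divisor)."""

    events: tuple[tuple[float, int], ...] = ()

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(t < 0 for t in times):
            raise ValueError("event times must be non-negative")
        if any(int(d) != d or d < 1 for _, d in self.events):
            raise ValueError("split divisors must be integers >= 1")

    @classmethod
    def regular(
        cls, interval_h: float = 36.0, divisor: int = 2, duration_h: float = 240.0
    ) -> "DilutionSchedule":
        """Split-in-``divisor`` every ``interval_h`` hours up to ``duration_h``."""
        n = int(duration_h // interval_h)
        return cls(tuple((interval_h * (k + 1), divisor) for k in range(n)))


def standard_schedule(duration_h: float = 240.0) -> DilutionSchedule:
    """The routine protocol: split in two every 36 h (factor 64 by day 10)."""
    return DilutionSchedule.regular(36.0, 2, duration_h)


def control_lc20_schedule() -> DilutionSchedule:
    """The extra-dilution control schedule for fast-growing wells.

    Cumulative division factors 64 at day 6, 128 at day 8, 512 at day 9
    and 2048 at day 10, on top of the routine 36 h splits before day 6.
    """
    return DilutionSchedule(
        (
            (36.0, 2),
            (72.0, 2),
            (108.0, 2),
            (144.0, 8),  # cumulative 64 at day 6
            (192.0, 2),  # 128 at day 8
            (216.0, 4),  # 512 at day 9
            (240.0, 4),  # 2048 at day 10
        )
    )


def cumulative_dilution_factor(schedule: DilutionSchedule, t_hours: float) -> int:
    """Product of split divisors of all events at or before ``t_hours``."""
    if t_hours < 0:
        raise ValueError("time must be non-negative")
    factor = 1
    for time, divisor in schedule.events:
        if time <= t_hours:
            factor *= int(divisor)
    return factor


@dataclass(frozen=True)
class PopulationSeries:
    """Counted (diluted) population sizes for one treatment x replicate."""

    treatment: str
    replicate: str | int
    days: tuple[float, ...]
    counted_n: tuple[int, ...]
    schedule: DilutionSchedule = field(default_factory=DilutionSchedule)

    def __post_init__(self) -> None:
        if len(self.days) != len(self.counted_n):
            raise ValueError("days and counted_n must have equal length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(n < 0 for n in self.counted_n):
            raise ValueError("counts must be non-negative")


def reconstruct_population(series: PopulationSeries) -> pd.DataFrame:
    """Scale counted wells back to the whole-population level.

    true_n(day) = counted_n x cumulative dilution factor at that day; the
    identity when the schedule is empty.
    """
    rows = []
    for day, counted in zip(series.days, series.counted_n):
        factor = cumulative_dilution_factor(series.schedule, 24.0 * day)
        rows.append(
            {
                "day": day,
                "counted_n": counted,
                "dilution_factor": factor,
                "true_n": counted * factor,
            }
        )
    return pd.DataFrame(rows)


_TRANSFORMS = ("log_pseudocount", "none")


def _transform(n: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log_pseudocount":
        return np.log10(n + 1.0)
    if transform == "none":
        return n.astype(float)
    raise ValueError(f"unknown transform {transform!r}; expected one of {_TRANSFORMS}")


def auc_population(
    days: Sequence[float],
    n: Sequence[float],
    transform: str = "log_pseudocount",
) -> float:
    """Trapezoid-rule area under the population-vs-time curve.

    With the default transform the integrand is log10(N + 1); the
    pseudo-count keeps extinct populations (N = 0) finite. Units are
    (log10 population) x days, or population x days untransformed.
    """
    days_arr = np.asarray(days, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if days_arr.size != n_arr.size:
        raise ValueError("days and n must have equal length")
    if days_arr.size < 2:
        raise EndpointError("at least two time points are required for an AUC")
    if np.any(np.diff(days_arr) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(n_arr < 0):
        raise ValueError("population sizes must be non-negative")
    return float(np.trapezoid(_transform(n_arr, transform), days_arr))


@dataclass(frozen=True)
class EndpointSummary:
    """The three population endpoints for one series."""

    auc: float
    max_n: float
    max_day: float
    end_n: float


def endpoint_summary(
    series: PopulationSeries,
    transform: str = "log_pseudocount",
    use_reconstructed: bool = True,
) -> EndpointSummary:
    """AUC, maximum (earliest day on ties) and end population of a series.

    By default the counted series is reconstructed to whole-population
    scale first; ``use_reconstructed=False`` operates on raw counts.
    """
    recon = reconstruct_population(series)
    n = recon["true_n"].to_numpy(dtype=float) if use_reconstructed else recon[
        "counted_n"
    ].to_numpy(dtype=float)
    days = recon["day"].to_numpy(dtype=float)
    auc = auc_population(days, n, transform=transform)
    idx = int(np.argmax(n))  # argmax returns the first occurrence on ties
    return EndpointSummary(
        auc=auc, max_n=float(n[idx]), max_day=float(days[idx]), end_n=float(n[-1])
    )


def endpoint_table(
    series_list: Sequence[PopulationSeries],
    transform: str = "log_pseudocount",
    use_reconstructed: bool = True,
) -> pd.DataFrame:
    """One endpoint row per treatment x replicate."""
    rows = []
    for s in series_list:
        summary = endpoint_summary(s, transform=transform, use_reconstructed=use_reconstructed)
        rows.append(
            {
                "treatment": s.treatment,
                "replicate": s.replicate,
                "auc": summary.auc,
                "max_n": summary.max_n,
                "max_day": summary.max_day,
                "end_n": summary.end_n,
            }
        )
    return pd.DataFrame(rows)


def percent_vs_control(
    treatment_value: float, control_value: float, convention: str = "smaller"
) -> float:
    """Signed percent difference relative to a control (or reference) value.

    ``smaller``: 100 x (control - treatment) / control, i.e. how much
    smaller the treatment is than the control ("80% smaller" = 80).
    ``larger``: 100 x (treatment - control) / control.
    """
    if control_value == 0:
        raise EndpointError("percent difference vs a zero control is undefined")
    if convention == "smaller":
        return 100.0 * (control_value - treatment_value) / control_value
    if convention == "larger":
        return 100.0 * (treatment_value - control_value) / control_value
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class MortalityRecord:
    """Founder-cohort mortality observation for one well."""

    treatment: str
    replicate: str | int
    time_h: float
    n_start: int
    n_alive: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_alive <= self.n_start):
            raise ValueError("need 0 <= n_alive <= n_start")


def mortality_fraction(rec: MortalityRecord) -> float:
    """Percent of the founder cohort dead at the record's time."""
    if rec.n_start == 0:
        raise EndpointError("mortality undefined for an empty founder cohort")
    return 100.0 * (rec.n_start - rec.n_alive) / rec.n_start


# ---------------------------------------------------------------------------
# group comparisons


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise ValueError("at least two groups are required")
    for label, values in out.items():
        if values.size < 1 or not np.all(np.isfinite(values)):
            raise ValueError(f"group {label!r} must contain finite values")
    return out


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    dunnett: pd.DataFrame | None


def anova_dunnett_tukey(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
) -> AnovaResult:
    """One-way ANOVA with Tukey all-pairs and Dunnett many-to-one post hocs.

    Dunnett comparisons (each group vs ``control``) use the
    equicorrelated multivariate-t critical values. When every observation
    is identical the degenerate answer F = 0, all adjusted p = 1 is
    returned rather than 0/0.
    """
    data = _as_groups(groups)
    for label, values in data.items():
        if values.size < 2:
            raise ValueError(f"group {label!r} needs at least 2 replicates")
    if control is not None and control not in data:
        raise KeyError(f"control label {control!r} not among groups")
    labels = list(data)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]

    all_values = np.concatenate(list(data.values()))
    if np.allclose(all_values, all_values[0]):
        tukey = pd.DataFrame(
            [
                {"group1": a, "group2": b, "estimate": 0.0, "p_adj": 1.0}
                for a, b in pairs
            ]
        )
        dunnett_df = None
        if control is not None:
            dunnett_df = pd.DataFrame(
                [
                    {"group": g, "estimate": 0.0, "p_adj": 1.0}
                    for g in labels
                    if g != control
                ]
            )
        return AnovaResult(0.0, 1.0, tukey, dunnett_df)

    f_stat, p_value = stats.f_oneway(*data.values())

    values = np.concatenate(list(data.values()))
    group_labels = np.concatenate([[lbl] * data[lbl].size for lbl in labels])
    hsd = pairwise_tukeyhsd(values, group_labels)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )[["group1", "group2", "meandiff", "p-adj"]].rename(
        columns={"meandiff": "estimate", "p-adj": "p_adj"}
    )

    dunnett_df = None
    if control is not None:
        others = [g for g in labels if g != control]
        res = stats.dunnett(*(data[g] for g in others), control=data[control])
        dunnett_df = pd.DataFrame(
            {
                "group": others,
                "estimate": [float(np.mean(data[g]) - np.mean(data[control])) for g in others],
                "p_adj": res.pvalue,
            }
        )
    return AnovaResult(float(f_stat), float(p_value), tukey, dunnett_df)


@dataclass(frozen=True)
class KruskalResult:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame


def kruskal_bonferroni(groups: Mapping[str, Sequence[float]]) -> KruskalResult:
    """Kruskal-Wallis H (tie-corrected) with Bonferroni pairwise rank sums.

    Pairwise comparisons are two-sided Mann-Whitney rank-sum tests (exact
    for small tie-free samples) with p multiplied by the number of
    comparisons and capped at 1. All-identical data return H = 0, p = 1.
    """
    data = _as_groups(groups)
    labels = list(data)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    all_values = np.concatenate(list(data.values()))
    if np.allclose(all_values, all_values[0]):
        pairwise = pd.DataFrame(
            [
                {"group1": a, "group2": b, "p_raw": 1.0, "p_adj": 1.0}
                for a, b in pairs
            ]
        )
        return KruskalResult(0.0, 1.0, pairwise)
    h, p = stats.kruskal(*data.values())
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if np.allclose(data[a], data[a][0]) and np.allclose(data[b], data[b][0]) and np.isclose(
            data[a][0], data[b][0]
        ):
            p_raw = 1.0
        else:
            p_raw = float(stats.mannwhitneyu(data[a], data[b], alternative="two-sided").pvalue)
        rows.append(
            {"group1": a, "group2": b, "p_raw": p_raw, "p_adj": min(1.0, p_raw * m)}
        )
    return KruskalResult(float(h), float(p), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# body-length regression


def length_slopes(lengths: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least-squares body-length slope (mm/day) per treatment.

    ``lengths`` needs columns treatment, day, length_mm (replicate is
    carried through if present but not modelled: the paper-style random
    intercept is replaced by per-treatment fixed-effect OLS).
    """
    required = {"treatment", "day", "length_mm"}
    missing = required - set(lengths.columns)
    if missing:
        raise ValueError(f"lengths table missing columns: {sorted(missing)}")
    rows = []
    for treatment, grp in lengths.groupby("treatment", sort=False):
        if grp["day"].nunique() < 2:
            raise EndpointError(
                f"treatment {treatment!r} needs at least two distinct days"
            )
        X = sm.add_constant(grp["day"].to_numpy(dtype=float))
        fit = sm.OLS(grp["length_mm"].to_numpy(dtype=float), X).fit()
        rows.append(
            {
                "treatment": treatment,
                "slope_mm_per_day": float(fit.params[1]),
                "slope_se": float(fit.bse[1]),
                "intercept_mm": float(fit.params[0]),
                "n": int(grp.shape[0]),
            }
        )
    return pd.DataFrame(rows)


def slope_contrast(
    lengths: pd.DataFrame, treatment_a: str, treatment_b: str
) -> dict[str, float]:
    """Difference in body-length slopes (a minus b) with its standard error.

    Estimated from the day x treatment interaction of a two-treatment
    fixed-effects regression; returns estimate, standard error and the
    interaction p-value.
    """
    sub = lengths[lengths["treatment"].isin([treatment_a, treatment_b])].copy()
    if sub["treatment"].nunique() != 2:
        raise ValueError("both treatments must be present in the table")
    sub["is_a"] = (sub["treatment"] == treatment_a).astype(float)
    day = sub["day"].to_numpy(dtype=float)
    is_a = sub["is_a"].to_numpy()
    X = sm.add_constant(np.column_stack([day, is_a, day * is_a]))
    fit = sm.OLS(sub["length_mm"].to_numpy(dtype=float), X).fit()
    return {
        "estimate": float(fit.params[3]),
        "se": float(fit.bse[3]),
        "p_value": float(fit.pvalues[3]),
    }
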