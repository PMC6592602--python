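"""Mixture-effect prediction (concentration addition / independent action)
and classification of observed mixture effects.

Concentration addition (CA) treats the components as dilutions of one
another: the predicted mixture effect y solves

    sum_i  c_i / ( EC50_i * (y / (100 - y))**(1 / beta_i) ) = 1,

i.e. the sum of toxic units at effect level y equals one. Independent
action (IA) multiplies survival probabilities:

    y = 100 * [ 1 - prod_i 1 / (1 + (c_i / EC50_i)**beta_i) ].

Both reduce to the single-compound curve at n = 1. The exponent in the CA
sum is applied per compound (1/beta_i), the standard generalisation; a
strict shared-slope mode is available through ``shared_beta``.

Observed replicate effects are compared against each model's prediction
with a one-sample Wilcoxon signed-rank test (exact sign-pattern
enumeration for small n, zeros discarded). An effect significantly above
both predictions is synergistic, significantly below both antagonistic,
anything else additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doseresponse import Concentration, LogLogisticCurve, UnitError, effect_at

__all__ = [
    "MixtureExposure",
    "MixturePrediction",
    "InteractionCall",
    "ConvergenceError",
    "predict_ca",
    "predict_ia",
    "predict",
    "signed_rank_test",
    "SignedRankResult",
    "classify_interaction",
    "ratio_profile",
]


class ConvergenceError(RuntimeError):
    """Raised when the CA root search fails to meet its tolerance."""


@dataclass(frozen=True)
class MixtureExposure:
    """An ordered list of (dose-response curve, concentration) components."""

    components: tuple[tuple[LogLogisticCurve, Concentration], ...]

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("a mixture needs at least one component")
        for curve, conc in self.components:
            if conc.unit != curve.ec50.unit:
                raise UnitError(
                    f"component dose unit {conc.unit!r} does not match its "
                    f"curve unit {curve.ec50.unit!r}"
                )

    @classmethod
    def of(cls, *components: tuple[LogLogisticCurve, Concentration]) -> "MixtureExposure":
        return cls(tuple(components))

    @property
    def n(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class MixturePrediction:
    """Predicted mixture effect under both models, with solver diagnostics."""

    y_ca: float
    y_ia: float
    iterations: int = 0
    residual: float = float("nan")


def predict_ia(mix: MixtureExposure) -> float:
    """Independent-action prediction: survivals multiply (closed form)."""
    log_surv = 0.0
    for curve, conc in mix.components:
        y = effect_at(curve, conc)
        log_surv += math.log1p(-y / 100.0)
    return 100.0 * (1.0 - math.exp(log_surv))


def _ca_toxic_units(
    mix: MixtureExposure, y: float, shared_beta: float | None
) -> float:
    """Left side of the CA identity: total toxic units at effect level y."""
    total = 0.0
    for curve, conc in mix.components:
        beta = shared_beta if shared_beta is not None else curve.beta
        # (y/(100-y))**(1/beta) on the log scale
        log_term = math.log(y / (100.0 - y)) / beta
        total += conc.value / (curve.ec50.value * math.exp(log_term))
    return total


def predict_ca(
    mix: MixtureExposure,
    tol: float = 1e-10,
    shared_beta: float | None = None,
    max_iter: int = 200,
) -> float:
    """Concentration-addition prediction by bracketed bisection on y.

    The toxic-unit sum is strictly decreasing in y, so the root on
    (0, 100) is unique whenever any component concentration is positive.
    An all-zero mixture returns 0 by convention. Deterministic; ``tol`` is
    an absolute tolerance on y (percent).
    """
    if all(conc.value == 0 for _, conc in mix.components):
        return 0.0
    lo, hi = 1e-9, 100.0 - 1e-9
    f_lo = _ca_toxic_units(mix, lo, shared_beta)
    f_hi = _ca_toxic_units(mix, hi, shared_beta)
    if f_lo < 1.0:  # effect below the bracket floor: essentially zero
        return lo
    if f_hi > 1.0:  # pinned against 100% within the bracket
        return hi
    iterations = 0
    while hi - lo > tol and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        if _ca_toxic_units(mix, mid, shared_beta) > 1.0:
            lo = mid
        else:
            hi = mid
        iterations += 1
    y = 0.5 * (lo + hi)
    residual = _ca_toxic_units(mix, y, shared_beta) - 1.0
    if hi - lo > tol:
        raise ConvergenceError(
            f"CA bisection did not reach tol={tol} in {max_iter} iterations "
            f"(bracket width {hi - lo:.3e}, residual {residual:.3e})"
        )
    return y


def predict(mix: MixtureExposure, tol: float = 1e-10) -> MixturePrediction:
    """Both model predictions for one mixture."""
    y_ca = predict_ca(mix, tol=tol)
    residual = (
        _ca_toxic_units(mix, y_ca, None) - 1.0
        if any(conc.value > 0 for _, conc in mix.components)
        else 0.0
    )
    return MixturePrediction(y_ca=y_ca, y_ia=predict_ia(mix), residual=residual)


# ---------------------------------------------------------------------------
# one-sample Wilcoxon signed-rank test (exact for small n)

_EXACT_LIMIT = 16  # 2**16 sign patterns is still cheap to enumerate


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    pvalue: float
    n: int  # non-zero differences used


def signed_rank_test(
    diffs: Sequence[float], alternative: str = "two-sided"
) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (classic Wilcoxon zero handling); ties
    among |differences| receive midranks. For n <= 16 the p-value comes
    from exact enumeration of all 2**n sign patterns (valid with ties);
    beyond that a tie-corrected normal approximation with continuity
    correction is used. ``alternative`` is 'greater' (median difference
    > 0), 'less', or 'two-sided'.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be one-dimensional")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(statistic=0.0, pvalue=1.0, n=0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_LIMIT:
        patterns = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        dist = patterns @ ranks
        eps = 1e-9
        p_greater = float(np.mean(dist >= w_plus - eps))
        p_less = float(np.mean(dist <= w_plus + eps))
    else:
        mean = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_sizes**3 - tie_sizes
        ) / 48.0
        sd = math.sqrt(var)
        p_greater = float(stats.norm.sf((w_plus - 0.5 - mean) / sd))
        p_less = float(stats.norm.cdf((w_plus + 0.5 - mean) / sd))
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return SignedRankResult(statistic=w_plus, pvalue=min(p, 1.0), n=n)


@dataclass(frozen=True)
class InteractionCall:
    """Classification of an observed mixture effect against both models."""

    label: str  # additive | antagonistic | synergistic
    p_vs_ca: float
    p_vs_ia: float
    direction_vs_ca: int  # sign of the median deviation from the CA prediction
    direction_vs_ia: int
    alpha: float
    n: int


def _one_sided_vs(observed: np.ndarray, predicted: float) -> tuple[float, int]:
    """One-sided signed-rank p in the direction of the median deviation."""
    d = observed - predicted
    direction = int(np.sign(np.median(d)))
    if direction > 0:
        p = signed_rank_test(d, alternative="greater").pvalue
    elif direction < 0:
        p = signed_rank_test(d, alternative="less").pvalue
    else:
        p = 1.0
    return p, direction


def classify_interaction(
    observed: Sequence[float],
    prediction: MixturePrediction,
    alpha: float = 0.05,
) -> InteractionCall:
    """Label an observed mixture effect additive, antagonistic or synergistic.

    The observed replicate effects (percent) are tested against each
    model's prediction treated as a constant. The call is synergistic only
    if the observed effect is significantly above BOTH predictions,
    antagonistic only if significantly below BOTH; discordant directions
    or non-significance collapse to additive.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 3:
        raise ValueError("at least 3 replicate effects are required")
    if np.any((obs < 0) | (obs > 100)):
        raise ValueError("effects must lie in [0, 100]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    p_ca, dir_ca = _one_sided_vs(obs, prediction.y_ca)
    p_ia, dir_ia = _one_sided_vs(obs, prediction.y_ia)
    if dir_ca > 0 and dir_ia > 0 and p_ca < alpha and p_ia < alpha:
        label = "synergistic"
    elif dir_ca < 0 and dir_ia < 0 and p_ca < alpha and p_ia < alpha:
        label = "antagonistic"
    else:
        label = "additive"
    return InteractionCall(
        label=label,
        p_vs_ca=p_ca,
        p_vs_ia=p_ia,
        direction_vs_ca=dir_ca,
        direction_vs_ia=dir_ia,
        alpha=alpha,
        n=obs.size,
    )


def ratio_profile(
    mixture_outcomes: Mapping[str, float] | pd.Series,
    reference_outcome: float,
) -> pd.Series:
    """Element-wise ratio of mixture outcomes to a single-compound reference.

    For mortality a ratio above 1 means greater toxicity in the mixture;
    for population size a ratio below 1 does. A zero (or negative)
    reference leaves the ratio undefined and raises ``ValueError``.
    """
    if not (reference_outcome > 0):
        raise ValueError(
            f"reference outcome must be strictly positive, got {reference_outcome}"
        )
    series = pd.Series(mixture_outcomes, dtype=float)
    return series / float(reference_outcome)
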