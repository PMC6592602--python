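"""Single-compound log-logistic dose-response curves and LC tables.

The two-parameter log-logistic model used throughout the package is

    y(c) = 100 * (c / EC50)**beta / (1 + (c / EC50)**beta)

with ``y`` a percent effect (mortality) in [0, 100), ``EC50`` the
concentration producing a 50% effect and ``beta`` the dimensionless slope.
On the logit scale the model is linear in log concentration,
``logit(y/100) = beta * (ln c - ln EC50)``, which is what the fitting
routines exploit.

Concentrations are carried with explicit units (mg/L, mM or uM) and are
converted on a metal-ion molar-mass basis; the canonical internal unit is
mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MG_PER_L",
    "MILLIMOLAR",
    "MICROMOLAR",
    "UnitError",
    "FitError",
    "CompoundId",
    "Concentration",
    "LogLogisticCurve",
    "LCTable",
    "FitResult",
    "ZINC",
    "COPPER",
    "CADMIUM",
    "COMPOUNDS",
    "convert_concentration",
    "effect_at",
    "lc_at",
    "fit_two_point",
    "fit_loglogistic",
    "read_lc_table",
    "write_lc_table",
    "load_reference_lc_table",
    "curve_from_lc_table",
]

MG_PER_L = "mg/L"
MILLIMOLAR = "mM"
MICROMOLAR = "uM"

_UNIT_ALIASES = {
    "mg/l": MG_PER_L,
    "mg per l": MG_PER_L,
    "mm": MILLIMOLAR,
    "um": MICROMOLAR,
    "µm": MICROMOLAR,  # micro sign
    "μm": MICROMOLAR,  # greek mu
}


class UnitError(ValueError):
    """Raised for unknown concentration units or unit mismatches."""


class FitError(ValueError):
    """Raised when a dose-response fit is degenerate or under-determined."""


def _normalise_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip().lower()]
    except (KeyError, AttributeError):
        raise UnitError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{MG_PER_L!r}, {MILLIMOLAR!r}, {MICROMOLAR!r}"
        ) from None


@dataclass(frozen=True)
class CompoundId:
    """A test compound identified by name and metal-ion molar mass (g/mol)."""

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")
        if not (self.molar_mass > 0 and math.isfinite(self.molar_mass)):
            raise ValueError("molar_mass must be a positive finite number")


# Metal-ion molar masses; exposures are expressed per free metal ion,
# not per salt (the mg/L <-> mM pairing in the reference LC table is
# consistent with atomic, not salt, masses).
ZINC = CompoundId("Zn", 65.38)
COPPER = CompoundId("Cu", 63.546)
CADMIUM = CompoundId("Cd", 112.414)
COMPOUNDS: Mapping[str, CompoundId] = {c.name: c for c in (ZINC, COPPER, CADMIUM)}


@dataclass(frozen=True)
class Concentration:
    """A non-negative concentration with an explicit unit."""

    value: float
    unit: str = MG_PER_L

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _normalise_unit(self.unit))
        if not (self.value >= 0 and math.isfinite(self.value)):
            raise ValueError(f"concentration must be finite and >= 0, got {self.value}")


def convert_concentration(
    c: Concentration, compound: CompoundId, target_unit: str
) -> Concentration:
    """Convert ``c`` between mg/L, mM and uM using the compound's molar mass.

    mg/L divided by molar mass (g/mol) gives mM; uM is 1000x mM. The
    round trip returns the input within floating tolerance.
    """
    target = _normalise_unit(target_unit)
    # via canonical mg/L
    if c.unit == MG_PER_L:
        mg_l = c.value
    elif c.unit == MILLIMOLAR:
        mg_l = c.value * compound.molar_mass
    else:  # uM
        mg_l = c.value * compound.molar_mass / 1000.0
    if target == MG_PER_L:
        out = mg_l
    elif target == MILLIMOLAR:
        out = mg_l / compound.molar_mass
    else:
        out = 1000.0 * mg_l / compound.molar_mass
    return Concentration(out, target)


@dataclass(frozen=True)
class LogLogisticCurve:
    """Two-parameter log-logistic dose-response curve for one compound."""

    compound: CompoundId
    ec50: Concentration
    beta: float

    def __post_init__(self) -> None:
        if not (self.ec50.value > 0):
            raise ValueError("ec50 must be strictly positive")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError("beta must be a positive finite number")

    def effect_at(self, c: Concentration) -> float:
        return effect_at(self, c)

    def lc_at(self, x: float) -> Concentration:
        return lc_at(self, x)


def effect_at(curve: LogLogisticCurve, c: Concentration) -> float:
    """Percent effect in [0, 100) at concentration ``c``.

    ``c`` must carry the same unit as the curve's EC50 (convert first);
    a mismatch raises :class:`UnitError` rather than silently mixing scales.
    """
    if c.unit != curve.ec50.unit:
        raise UnitError(
            f"dose unit {c.unit!r} does not match curve unit {curve.ec50.unit!r}; "
            "use convert_concentration first"
        )
    if c.value == 0:
        return 0.0
    # work on the log scale to keep extreme doses well conditioned
    log_r = curve.beta * (math.log(c.value) - math.log(curve.ec50.value))
    if log_r > 0:
        y = 100.0 / (1.0 + math.exp(-log_r))
        # keep the effect strictly below 100 even when floats saturate
        return min(y, math.nextafter(100.0, 0.0))
    r = math.exp(log_r)
    return 100.0 * r / (1.0 + r)


def lc_at(curve: LogLogisticCurve, x: float) -> Concentration:
    """Concentration producing effect ``x`` percent (the LCx), closed form."""
    if not (0 < x < 100):
        raise ValueError(f"LC level must lie strictly between 0 and 100, got {x}")
    value = curve.ec50.value * (x / (100.0 - x)) ** (1.0 / curve.beta)
    return Concentration(value, curve.ec50.unit)


def fit_two_point(
    p1: tuple[Concentration, float],
    p2: tuple[Concentration, float],
    compound: CompoundId | None = None,
) -> LogLogisticCurve:
    """Exactly identify (EC50, beta) from two (concentration, effect%) points.

    beta = ln[(y2/(100-y2)) / (y1/(100-y1))] / ln(c2/c1) and EC50 follows
    from either point; the resulting curve passes through both inputs.
    """
    (c1, y1), (c2, y2) = p1, p2
    if c1.unit != c2.unit:
        raise UnitError("both points must use the same concentration unit")
    for y in (y1, y2):
        if not (0 < y < 100):
            raise FitError(f"effects must lie strictly in (0, 100), got {y}")
    if c1.value <= 0 or c2.value <= 0:
        raise FitError("concentrations must be strictly positive")
    if c1.value == c2.value:
        raise FitError("degenerate fit: the two concentrations are equal")
    if y1 == y2:
        raise FitError("degenerate fit: the two effects are equal")
    logit1 = math.log(y1 / (100.0 - y1))
    logit2 = math.log(y2 / (100.0 - y2))
    beta = (logit2 - logit1) / (math.log(c2.value) - math.log(c1.value))
    if beta <= 0:
        raise FitError("effects must increase with concentration (beta > 0)")
    ln_ec50 = math.log(c1.value) - logit1 / beta
    cmpd = compound or CompoundId("?", 1.0)
    return LogLogisticCurve(cmpd, Concentration(math.exp(ln_ec50), c1.unit), beta)


@dataclass(frozen=True)
class FitResult:
    """A fitted curve plus least-squares diagnostics."""

    curve: LogLogisticCurve
    rss: float
    n_points: int
    converged: bool


def fit_loglogistic(
    points: Sequence[tuple[Concentration, float]],
    weights: Sequence[float] | None = None,
    compound: CompoundId | None = None,
) -> FitResult:
    """Least-squares fit of (EC50, beta) to (concentration, effect%) points.

    The optimiser works on (log10 EC50, log10 beta) so both parameters stay
    positive without constraint machinery, and is multistarted from the
    two-point fit of the extreme doses and from a logit-linear regression.
    With exactly two points the result reproduces :func:`fit_two_point`.

    ``weights`` are inverse-variance weights on the percent-effect scale
    (e.g. ``n * p * (1 - p) / 100**2`` reciprocals for binomial mortality
    data); unweighted by default.
    """
    if len(points) < 2:
        raise FitError("at least two dose-effect points are required")
    units = {c.unit for c, _ in points}
    if len(units) != 1:
        raise UnitError("all points must share one concentration unit")
    unit = units.pop()
    conc = np.array([c.value for c, _ in points], dtype=float)
    eff = np.array([y for _, y in points], dtype=float)
    if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(eff)):
        raise FitError("non-finite inputs")
    if np.any(conc <= 0):
        raise FitError("concentrations must be strictly positive")
    if np.any((eff <= 0) | (eff >= 100)):
        raise FitError("effects must lie strictly in (0, 100)")
    cmpd = compound or CompoundId("?", 1.0)

    if len(points) == 2:
        curve = fit_two_point(points[0], points[1], compound=cmpd)
        return FitResult(curve=curve, rss=0.0, n_points=2, converged=True)

    if weights is None:
        w = np.ones_like(eff)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != eff.shape or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise FitError("weights must be positive, finite and match points")
    sqrt_w = np.sqrt(w)

    def residuals(theta: np.ndarray) -> np.ndarray:
        ec50 = 10.0 ** theta[0]
        beta = 10.0 ** theta[1]
        log_r = beta * (np.log(conc) - math.log(ec50))
        y = 100.0 / (1.0 + np.exp(-log_r))
        return sqrt_w * (y - eff)

    starts: list[tuple[float, float]] = []
    # logit-linear regression start
    x = np.log(conc)
    z = np.log(eff / (100.0 - eff))
    slope, intercept = np.polyfit(x, z, 1)
    if slope > 0:
        starts.append((math.exp(-intercept / slope), slope))
    # two-point start from the extreme doses
    i, j = int(np.argmin(conc)), int(np.argmax(conc))
    if eff[i] != eff[j]:
        try:
            two = fit_two_point(points[i], points[j], compound=cmpd)
            starts.append((two.ec50.value, two.beta))
        except FitError:
            pass
    if not starts:
        starts.append((float(np.exp(np.mean(x))), 1.0))

    best = None
    for ec50_0, beta_0 in starts:
        theta0 = np.array([math.log10(ec50_0), math.log10(beta_0)])
        sol = optimize.least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    ec50 = 10.0 ** best.x[0]
    beta = 10.0 ** best.x[1]
    curve = LogLogisticCurve(cmpd, Concentration(ec50, unit), beta)
    rss = float(np.sum(best.fun**2))
    return FitResult(curve=curve, rss=rss, n_points=len(points), converged=bool(best.success))


@dataclass(frozen=True)
class LCTable:
    """LC levels (percent) mapped to concentrations for one compound.

    ``spreads`` carries the published +/- values as annotation only; no
    inference is done with them.
    """

    compound: CompoundId
    entries: Mapping[float, Concentration]
    spreads: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = sorted(self.entries)
        if not levels:
            raise ValueError("LC table must contain at least one entry")
        for x in levels:
            if not (0 < x < 100):
                raise ValueError(f"LC level must be in (0, 100), got {x}")
        values = [self.entries[x].value for x in levels]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError("LC concentrations must increase strictly with level")
        units = {self.entries[x].unit for x in levels}
        if len(units) != 1:
            raise UnitError("all LC entries must share one unit")

    @property
    def levels(self) -> list[float]:
        return sorted(self.entries)

    def concentration(self, level: float) -> Concentration:
        try:
            return self.entries[level]
        except KeyError:
            raise KeyError(f"no LC{level:g} entry for {self.compound.name}") from None


def curve_from_lc_table(table: LCTable) -> LogLogisticCurve:
    """Fit a log-logistic curve to an LC table.

    With exactly two entries the curve is exactly identified; with more it
    is the least-squares fit over all printed levels.
    """
    points = [(table.entries[x], x) for x in table.levels]
    if len(points) == 2:
        return fit_two_point(points[0], points[1], compound=table.compound)
    return fit_loglogistic(points, compound=table.compound).curve


def read_lc_table(path) -> dict[str, LCTable]:
    """Read LC tables from CSV (compound, lc_level, conc_mg_per_L[, conc_spread])."""
    df = pd.read_csv(path)
    required = {"compound", "lc_level", "conc_mg_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"LC table CSV missing columns: {sorted(missing)}")
    tables: dict[str, LCTable] = {}
    for name, grp in df.groupby("compound", sort=False):
        compound = COMPOUNDS.get(str(name), CompoundId(str(name), 1.0))
        entries = {
            float(r.lc_level): Concentration(float(r.conc_mg_per_L), MG_PER_L)
            for r in grp.itertuples()
        }
        spreads = {}
        if "conc_spread" in grp.columns:
            spreads = {
                float(r.lc_level): float(r.conc_spread)
                for r in grp.itertuples()
                if pd.notna(r.conc_spread)
            }
        tables[str(name)] = LCTable(compound=compound, entries=entries, spreads=spreads)
    return tables


def write_lc_table(tables: Iterable[LCTable], path) -> None:
    rows = []
    for table in tables:
        for level in table.levels:
            rows.append(
                {
                    "compound": table.compound.name,
                    "lc_level": level,
                    "conc_mg_per_L": table.entries[level].value,
                    "conc_spread": table.spreads.get(level, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_lc_table() -> dict[str, LCTable]:
    """The packaged 24 h LC table for Zn, Cu and Cd (adult C. elegans)."""
    with resources.files("nemamix.data").joinpath("lc_table1.csv").open("r") as fh:
        return read_lc_table(fh)
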