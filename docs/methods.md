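# Methods

`nemamix` analyses metal-mixture toxicity experiments on *Caenorhabditis
elegans* of the kind run in liquid K-medium well plates: ~10 adult
founders per well, populations followed for 10–12 days with periodic
split-in-two transfers, body lengths of the most developed worms
measured on sampling days, and short (24–48 h) founder-mortality assays
for mixtures of Zn, Cu and Cd. This note records the models, the
parameter choices that matter, and the known limits of the synthetic
data the package generates.

## Dose–response model

Single-compound 24 h mortality is modelled as a two-parameter
log-logistic curve

    y(c) = 100 (c/EC50)^β / (1 + (c/EC50)^β),

with `y` a percent effect, `EC50 > 0` and slope `β > 0`. On the logit
scale this is linear in log concentration, so the LCx inverse has the
closed form `LCx = EC50 (x/(100−x))^{1/β}` and two distinct
(concentration, effect) points identify the curve exactly
(`fit_two_point`). `fit_loglogistic` minimises (optionally weighted)
squared percent-effect residuals over `(log10 EC50, log10 β)` — the log
parameterisation enforces positivity without constrained optimisation —
multistarted from the two-point fit of the extreme doses and from a
logit-linear regression. For binomial mortality data the recommended
weights are the inverse binomial variances `n p(1−p)/100²` reciprocals;
this makes the estimator asymptotically equivalent to the logistic-
regression MLE.

Concentrations carry explicit units (mg/L, mM, µM) and convert on a
metal-ion molar-mass basis (Zn 65.38, Cu 63.546, Cd 112.414 g/mol);
these masses were checked against the packaged LC table's own
mg/L ↔ mM column pairs, which are consistent with atomic rather than
salt masses. The canonical internal unit is mg/L; mixing units in one
computation is a hard error rather than a silent conversion.

The packaged reference LC table (24 h, adult worms) has five levels for
Zn (LC2–LC60) and two (LC5, LC20) for Cu and Cd. The Zn curve is the
least-squares fit over all five levels (EC50 ≈ 51.7 mg/L, β ≈ 0.819 —
the five printed levels are in fact almost exactly collinear on the
logit scale); Cu and Cd are exactly identified from their two levels
(Cd: EC50 ≈ 79.1 mg/L, β ≈ 0.575). Two-point curves extrapolate far
beyond the printed levels, and no claim is made that they reproduce
unprinted LC values; the shallow Cd slope in particular is an
extrapolation artefact to keep in mind when reading CA predictions.

## Mixture models

Concentration addition (CA) solves `Σ c_i / (EC50_i ·
(y/(100−y))^{1/β_i}) = 1` for `y` — the toxic-unit sum at the predicted
effect level equals one. The exponent is applied per compound
(`1/β_i`); this is the standard generalisation when slopes differ and
reduces correctly to the single curve at n = 1. A strict shared-slope
mode (`shared_beta`) is available for the textbook single-β form. The
left side is strictly decreasing in `y`, so the root is unique; it is
found by plain bisection on `y ∈ [10⁻⁹, 100−10⁻⁹]` percent to an
absolute tolerance of 10⁻¹⁰ — deterministic, no randomness, ~50
iterations. An all-zero mixture returns 0 by convention. Independent
action (IA) is the closed form `y = 100[1 − Π (1 + (c_i/EC50_i)^{β_i})⁻¹]`
(survival probabilities multiply).

CA is sham-additive (splitting one compound's dose across k components
changes nothing) and both predictions are non-decreasing in every
component. A point worth recording: the often-quoted rule "CA predicts
at least IA below the EC50" holds for steep slopes but *inverts* for
shallow ones (e.g. two equal compounds with β = 1 at 0.25 EC50 give
CA = 33.3% < IA = 36.0%). With the shallow fitted Cd/Zn slopes here, CA
is the lower — and therefore binding — prediction for antagonism calls.

## Interaction classification

Observed replicate effects are compared against each model's prediction
(a constant) with a one-sample Wilcoxon signed-rank test: zero
differences discarded, midranks for ties, exact enumeration of all 2^n
sign patterns for n ≤ 16 (valid under ties), tie-corrected normal
approximation with continuity correction beyond. Two one-sided tests at
level α establish direction. A mixture is *synergistic* if observed is
significantly above both the CA and IA predictions, *antagonistic* if
significantly below both, otherwise *additive*; discordant directions
collapse to additive. With six replicates the smallest attainable
one-sided p is 1/64 ≈ 0.0156, so a single α = 0.05 call requires at
least five concordant replicates. Classification is per time point
(24 h and 48 h reported separately); no multiplicity correction is
applied across Zn levels, matching the per-mixture presentation such
tables conventionally use. 48 h predictions extend the 24 h model
effect under the constant-hazard assumption,
`y₄₈ = 100(1 − (1 − y₂₄/100)²)`.

## Population endpoints and dilution bookkeeping

Counted wells are related to whole-population scale by the cumulative
product of split divisors at or before the counting time: the routine
protocol (split in two every 36 h) reaches 64× by day 10, and the
fast-growing control's override schedule reaches 64× at day 6, 128× at
day 8, 512× at day 9 and 2048× at day 10. Reconstruction (count ×
cumulative factor) is applied *before* endpoint computation by default —
reconstructed control populations are of order 10⁵–10⁶ by day 10 — with
a flag to operate on raw counts instead.

The three endpoints per series are (i) the trapezoid-rule area under
the population-vs-time curve computed on `log10(N+1)` — base 10 with a
pseudo-count of one so extinct wells (N = 0) stay finite; both the
transform and `none` are config switches — (ii) the maximum population
attained, ties broken by the earliest day ("maximum attained" read as
first attainment), and (iii) the end-of-experiment population.

Group comparisons: one-way ANOVA with Dunnett many-to-one (scipy's
multivariate-t implementation, cross-checked against R `multcomp` to
three decimals on a frozen dataset) and Tukey HSD all-pairs
(statsmodels); Kruskal–Wallis with tie correction and Bonferroni-
multiplied pairwise exact rank-sum tests for mortality fractions. The
degenerate all-identical case returns F = 0 (or H = 0) with p = 1
instead of 0/0. Body-length time trends use per-treatment OLS slopes
(mm/day) with slope differences estimated from the day × treatment
interaction of a two-treatment fixed-effects regression. This is a
deliberate simplification of a repeated-measures random-intercept
model: with ~20 worms × 3 replicates × 3–4 days per treatment the OLS
point estimate of the slope is identical and only the standard error
is mildly optimistic; population growth-rate estimation is likewise out
of scope (multi-generation trajectories are not well summarised by one
rate).

## The population simulator

The simulator is the package's synthetic-data generator and
parameter-recovery testbed. Time advances in 1 h steps (transfer times
and the 24 h LC window are integer multiples); individuals are grouped
by stage and age-in-stage, so cost scales with the number of cohorts,
not worms. Defaults and their anchors:

- **Stages**: egg 16 h, L1 16 h, L2 12 h, L3 12 h, L4 16 h → 72 h
  egg-to-adult, within the species' 3–4 day generation time at 20 °C.
  Stage lengths 0.25/0.37/0.55/0.80/1.20 mm (L1→adult), anchored to
  0.37 mm at the first molt, ~1.06 mm at egg-laying onset and 1–1.5 mm
  adults.
- **Reproduction**: 50 eggs/adult/day over a 4-day fertile window
  (≈200-egg self-fertile brood); founders are already fertile at t = 0,
  offspring begin laying 24 h into adulthood; adults live 14 days.
- **Hazard**: a 24 h mortality fraction y maps to the constant hazard
  h = −ln(1 − y/100)/24 h. Per-hour survival is exp(−h·m_s) with stage
  sensitivities egg 0.2 (shell-protected), larvae 2.5, adults 1.0.
- **Sub-lethal effects**: with s the 24 h kill fraction, stage durations
  scale by (1 + 5s) and fecundity by max(0, 1 − 4.5s). These
  coefficients, together with the larval sensitivity, were calibrated
  once to the qualitative single-metal pattern the assay shows at LC20:
  one new generation forms, the population peaks around day 2–4, and a
  Cd-LC20 well counts zero worms before day 10, while LC5 populations
  keep growing. They are declared assumptions, not estimates from data.
- **Transfers** subsample every cohort binomially with probability
  1/divisor at each schedule event; splits never create individuals.
- **Founders** are tracked separately so founder-cohort mortality (the
  quantity scored in the short ZnCd assays) is exact.
- **Expectation mode** (`deterministic=True`) propagates expected values
  through the identical update rules; it agrees with the across-seed
  mean of sampling mode and makes the dilution round trip exact, which
  the tests exploit as a closed-form oracle.

Hazard combination modes: `IA` sums hazards (the 24 h survival product
is then exactly the IA prediction), `CA` converts the CA-predicted
mixture effect to one hazard, and `protective_zn_cd` multiplies Cd's
effective concentration by a U-shaped factor g(c_Zn) while Zn's own
hazard always acts.

**Protective-mode shape.** g falls from 1 with a Hill decline
(half-protection at 0.45 mg/L Zn ≈ the Zn LC2, Hill coefficient 2.5) to
a floor g_min = 0.02, and recovers sharply above the Zn-overload
concentration (65.38 mg/L = 1 mM, Hill 6), so protection is
near-complete from roughly the Zn LC5 through the LC40 and largely lost
at the LC60. These constants encode the observed phenomenology: mixture
mortality at low-to-mid Zn sits at or below the Cd-only level (ratio
profiles dip below 1 before rising past it at overload), the strongest
antagonism falls in the LC20–LC40 range, and the protection loss
coincides with the ~1 mM saturation of inducible Zn-buffering capacity.
A deep floor is also a mathematical necessity, not merely a stylistic
choice: with the shallow fitted slopes, the CA prediction for
Zn-LC40 + Cd-LC20 (≈43.1%) sits only ~3 points above Zn-only mortality
(40.0%), so expected mixture mortality can only fall below *both* model
predictions across the LC5–LC40 range if Cd's contribution is almost
fully suppressed (g ≲ 0.07 at the LC40); a moderate floor such as 0.25
provably cannot produce the antagonistic signature against these
curves.

What the generator does *not* emulate: dauer formation, males,
matricidal hatching, bacterial food dynamics (food is assumed
unlimited, as the transfer protocol ensures), toxicokinetics and
time-varying internal dose, density dependence, and between-replicate
heterogeneity beyond demographic (binomial/Poisson) noise. Passing
tests therefore show that the *analysis* recovers known structure from
data with the experiment's design, sampling noise and dilution
protocol — not that real populations follow these update rules.

## Numerical and design notes

- Effects are percentages in [0, 100) throughout, never fractions; the
  logistic is evaluated on the log scale and clamped one ulp below 100
  so downstream `log1p(−y/100)` hazards stay finite.
- CA bisection: bracket [10⁻⁹, 100−10⁻⁹], |Δy| ≤ 10⁻¹⁰, verified
  against a 0.001-percent brute-force grid on random mixtures.
- The exact signed-rank enumeration is limited to n ≤ 16 (2¹⁶ patterns);
  the assays here have n = 6–12.
- Simulation studies in tests and the acceptance script use 10–100
  seeded replicates (e.g. 100 refits for parameter recovery, 20 runs of
  the ZnCd series), sizes chosen to make the pass criteria sharp while
  keeping a default run fast.
- All randomness flows through `numpy.random.default_rng` seeds derived
  with `SeedSequence`; fixed seeds give byte-identical generated CSVs.

## Known limitations

- Two-point Cu/Cd curves extrapolate; LC levels far from the fitted
  pair (including the EC50 itself) are not validated observables.
- No confidence intervals on LC values (the published ± spreads are
  carried as annotation only); no hormesis or biphasic models.
- The full dose-ratio/dose-level deviation framework for mixtures is
  out of scope; only CA/IA prediction plus the both-models
  classification rule is implemented.
- The protective mode is phenomenological — it models the shape of the
  Zn–Cd interaction, not its transporter-level mechanism.
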