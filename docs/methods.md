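# Methods

## Scope and model set

`tpcfit` treats the thermal performance curve (TPC) as a regression
problem: a unimodal rate response r(T) observed with additive noise at a
set of test temperatures. Twelve full-range equations are registered
(ids 4–15), spanning three families:

1. **Thermodynamic** (ids 4–7): rates controlled by Arrhenius-type
   activation opposed by reversible denaturation of a rate-limiting
   process. Temperature enters in kelvin (converted internally from °C);
   energy-like parameters are expressed in J mol⁻¹ with
   R = 8.314 J mol⁻¹ K⁻¹. The source literature never fixes these units —
   any consistent choice rescales the parameters without changing the
   fitted curve.
2. **Empirical peaked forms** (ids 8–12): Gaussian, modified Gaussian
   (free decay exponent), exponential-times-quadratic (Norberg/Eppley
   form), quadratic, and reciprocal-quadratic (Flinn).
3. **Fitted-limit forms** (ids 13–15): Ratkowsky (squared square-root
   model), Kamykowski, and a modified sine, which carry the thermal
   limits T_min/T_max (and for the sine, R_max) as fitted parameters and
   are exactly zero at those limits.

Two typeset ambiguities in the printed forms were resolved against the
original formulations: in the Ratkowsky form the square applies to each
factor (equivalently to the whole product), and the Johnson–Eyring
denominator is `1 + exp(−c/R)·exp(−d/(R·T))`, algebraically identical to
`1 + exp(−(c + d/T)/R)` (this identity is enforced as a test). The
modified sine is defined as zero outside [T_min, T_max], where the
fractional power of the reduced temperature would otherwise be
undefined; this extension is continuous and keeps least squares
well-behaved when the fitted limits cross data points during iteration.

A registry consequence worth noting: the *asymptotic* flag (no finite
zero crossings, hence CT_min/CT_max undefined) covers the Gaussian and
modified Gaussian, and also the Flinn form — a reciprocal quadratic
never reaches zero, and a numeric root search on it would latch onto
denominator poles instead.

Equations 5 and 7 are reparameterizations of the same four-parameter
family (both reduce to `A·T·e^(−β/T)/(1 + e^(γ−δ/T))`). They are kept
as separate registry entries because their parameterizations carry
different interpretations and starting-value conventions, but their
fitted curves coincide on any dataset; see "Limitations".

## Data preparation

Raw tables hold one row per (curve, temperature, replicate). Replicate
rates are averaged per temperature *first*; temperatures whose mean rate
is ≤ 0 are then removed (so replicates {+0.1, −0.1} average to zero and
drop). Zero and negative rates beyond the thermal limits have high
leverage on asymptotic/exponential forms and degrade the fit inside the
biokinetic range. Temperatures are de-duplicated after rounding to
10⁻⁶ °C to absorb text-format noise. A curve qualifies for full-range
fitting when it has ≥ 7 positive temperatures with ≥ 2 strictly on each
side of the observed maximum (ties broken toward the lower temperature).

## Fitting

Each equation is fitted by Levenberg–Marquardt least squares (MINPACK
through `lmfit`), unweighted (replicate counts are discarded after
averaging). Starting values are data-driven where a parameter has a data
analogue — amplitudes at the maximum observed rate, T_ref at the mean
temperature, T_min/T_max at the observed extremes — and otherwise come
from registered per-model defaults chosen so the initial curve is a
downward-parabola-like response over 0–40 °C peaking near 25 °C at a
rate of order one per day.

Numerical choices:

- Strictly positive scale parameters spanning many orders of magnitude
  (the Arrhenius pre-factors of ids 4–5) are fitted on a log scale
  internally; MINPACK's relative-step convergence tests are unreliable
  on them otherwise. Reported parameters are on the natural scale.
- Non-finite model output during iteration is replaced by a large
  residual penalty (10⁶) rather than raising.
- On failure, up to 10 restarts apply multiplicative log-normal jitter
  (σ = 0.5) to the start vector, with a seed derived deterministically
  from (random_state, model id): repeated runs are bitwise identical.
- Each attempt is capped at 3000 function evaluations. The
  double-Arrhenius form (id 4) has a degenerate likelihood ridge on
  negatively skewed data (a, c → ∞ with b → d): the infimum is
  approached but never attained, so the optimizer always exhausts its
  budget while the fitted curve itself stops changing. Such fits are
  polished and accepted at the stall/budget point, flagged
  "accepted at stall" / "accepted at evaluation budget". This mirrors
  how iteration-capped MINPACK pipelines behave in practice, and the
  equation remains usable (and typically worst-ranked) downstream.
- A numerically perfect fit (rss = 0) is flagged "degenerate perfect
  fit" and its criteria are evaluated at a tiny floor (10⁻³⁰⁰) so that
  ranking remains well defined (a perfect fit ranks first).

Model comparison uses BIC ranks (ties broken toward fewer parameters,
then lower id), AIC-based Akaike weights (the conventional basis for
weights even though ranking uses BIC), a tie-corrected Kruskal–Wallis
test on per-dataset ranks pooled by model, Nemenyi-type post hoc pairs
via the studentized range distribution, and Ward clustering of the
per-temperature prediction vectors (Euclidean distances).

## Cardinal temperatures and shape

- **T_opt**: coarse 2001-point scan of the search window followed by
  bounded scalar minimization (tolerance well below the 10⁻⁴ °C
  contract). The default window is the fitted data range padded by one
  range-width on each side; for equations with fitted thermal limits the
  window is clipped to [T_min, T_max] (outside it the Ratkowsky form
  rises again and the sine is identically zero, so a global scan would
  report a spurious optimum). A maximum on the window boundary is
  flagged rather than silently returned — estimates of T_opt are known
  to be drawn toward the centre of the measured range, and a boundary
  optimum usually signals exactly that pathology.
- **T50 limits**: nearest crossings of half the maximum rate on each
  side of T_opt, located by outward scanning and Brent refinement.
- **CT limits**: fitted T_min/T_max for ids 13–15; undefined for
  asymptotic forms; otherwise the nearest zero crossings around T_opt.
- **Activation / deactivation / skew**: mean of dRate/dT over a uniform
  100-point grid on (lower bound, T_opt) and (T_opt, upper bound),
  both kept signed; skew is their sum, so skew < 0 exactly when the
  supra-optimal decline is steeper than the sub-optimal rise. Bounds
  fall back from CT limits to T50 limits to the data extremes when
  undefined, and the choice is recorded per estimate (`bound_source`).
  The grid mean converges to the secant slope as density grows — a
  property the tests exploit as an oracle.
- **Consensus**: Akaike-weighted means per quantity over the models
  where it is defined, weights renormalized over that subset (undefined
  CT limits of asymptotic models would otherwise poison the mean);
  per-model signed deviations; and each model's mean absolute deviation
  from the weighted-mean predicted curve, in rate units and as % of the
  consensus maximum.

Derivatives are analytic where implemented (ids 8, 10–14) and central
finite differences with step 10⁻⁴ °C elsewhere; both routes are
cross-checked against each other in the tests.

## Data-quality engines

**Distinguishability.** From each converged fit, datasets are simulated
as prediction + Normal(0, σ̂) noise at the observed temperatures, with
σ̂ = sqrt(rss/n) from that fit; every equation is refitted to every
simulated dataset and ranked by BIC (five replicates per generator by
default). Non-positive draws are redrawn (up to 100 times per point)
rather than clipped, because downstream fitting requires positive rates
and clipping would bias σ̂.

**Sensitivity.** A curve is degraded either by random subsampling to n
temperatures (without replacement; by default at least one point is
retained on each side of the observed maximum so the curve stays
two-sided — pure uniform sampling is available via a flag) or by
truncating to the points whose rate reaches the top p of the rate scale
(`rate ≥ (1 − p)·max`). The refitted curve is compared to the full-data
fit: t_opt error is the absolute shift of the optimum; rate error is
the mean absolute prediction difference over the full curve's
temperatures as % of the full fit's maximum. Thresholds default to
0.5 °C and 5 %. The critical number of temperatures is the largest
count whose mean error exceeds its threshold, plus one; the critical
range is the smallest tested range strictly wider than the largest
range whose mean error met or exceeded the threshold (grid granularity
bounds the answer; the symmetric operationalization matches the count
rule). When no design value trips the threshold, the smallest tested
value is returned, flagged. Default design grids: counts from
n_params + 2 to the full count in steps of 1; ranges 10–100 % in steps
of 10 %; 10 replicates for random subsampling. Across species, errors
are aggregated by unweighted means (each curve a replicate).

## Synthetic data

The generator emulates high-resolution laboratory growth experiments:
seven species-like curves from the modified sine equation with skew
parameter a > 1 (negatively skewed truth), 18–39 temperatures at
0.4–0.5 °C increments, the window covering both sides of the optimum but
shifted a quarter-width toward the warm side (so the steep supra-optimal
limb is sampled), two replicates per temperature, and additive Gaussian
noise with σ = 5 % of the true maximum rate — a round value in the range
of replicate scatter typical of fluorometric growth assays. Per-model
presets provide a plausible unimodal parameterization of every equation
(peaks in the low-to-mid 20s °C at rates of order 1 day⁻¹) for
round-trip testing; for the thermodynamic equations the presets equal
the registered default start vectors.

What the generator does *not* emulate: temperature-dependent error
variance, replicate-level autocorrelation, acclimation or exposure-
duration effects, and measurement error in temperature itself. Passing
tests therefore demonstrate the correctness and internal consistency of
the pipeline under the stated noise model, not robustness to those
real-data features.

The paired temperature grids are cosine latitudinal gradients with
seeded noise and a uniform warming offset, masked identically — a
structural stand-in for gridded sea-surface temperature products,
sufficient for exercising the projection arithmetic but carrying no
climatology.

## Projection

Fitted curves are evaluated cellwise on a temperature grid; negative
predictions are floored at zero by default (a negative growth
contribution has no meaning in comparative maps), with raw values behind
`clamp_negative=False`. Per-decade change is (future − present)/n_decades,
additive, with n_decades supplied by the caller (midpoint-to-midpoint
2011→2100 gives 8.9). Global means are unweighted over unmasked cells by
default; cos-latitude area weighting is available behind a flag. Both
toggles should be reported with any result, as either convention is
defensible.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed and is exactly
reproducible. The shipped test suite and the acceptance script run the
pipeline at desk scale — seven curves of 18–39 temperatures, five
simulation replicates per generator, ten to twenty subsampling
replicates per design point — sizes chosen so a full from-scratch run
completes in minutes on one CPU while still exercising every code path
at the fidelity of the synthetic study design.

## Known limitations

- Equations 5 and 7 are the same function family in different
  parameterizations: their fits coincide on any dataset, so BIC cannot
  distinguish them and simulation-based self-identification between
  them reduces to a tie broken by optimization noise. Several other
  pairs (8/9, 13/15) can fall within a fraction of the noise scale of
  each other on smooth synthetic curves, with the same consequence.
- No confidence intervals on parameters or cardinal temperatures are
  provided: bootstrap resampling refits on effectively smaller designs
  (underestimating variance), and naive Monte-Carlo propagation ignores
  the strong parameter covariances (overestimating it). The sensitivity
  engine is the package's answer to "how much should I trust this
  estimate" — it measures how estimates move as data quality degrades.
- The double-Arrhenius form's degenerate ridge means its reported
  parameters are stopping-point dependent even though its fitted curve
  is stable; interpret them mechanistically with caution.
- Projection assumes growth depends on temperature alone — no nutrient
  colimitation, interactions, transport, or evolution.
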