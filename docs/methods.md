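# Methods

This note documents the statistical procedures implemented in `mixtox`,
the choices made where the underlying methodology left the design open,
and what the synthetic-data generator does and does not emulate.

## Benchmark-concentration estimation (`mixtox.bmc`)

A benchmark concentration (BMC) is the concentration at which a
readout's response first reaches its benchmark response (BMR) — the
per-readout magnitude defining an adverse effect, tabulated per worm
type, exposure day and direction in the packaged
`benchmark_responses` table.  The estimator is a Curvep-style
re-implementation; it follows the same outline as the published
bootstrap BMC pipelines but does not claim numeric parity with any
external package.

Per (readout, direction) series:

1. **Resampling unit = animal.** Each bootstrap iteration resamples
   animals with replacement within every concentration group, solvent
   controls included (n = 1,000 iterations by default; fewer than 100
   raises a quality flag).
2. **Summaries.** Incidence readouts: percent of animals responding.
   Continuous readouts: signed percent change of the per-concentration
   mean from the pooled control mean, re-signed per direction so each
   directional series measures response magnitude in its own direction
   (responses in the opposite direction are negative and never cross).
   A zero control mean makes a ratio-normalised readout unusable; it is
   flagged and skipped rather than silently dropped.
3. **Monotonisation (default on).** Pool-adjacent-violators enforces a
   non-decreasing response in concentration.  The switch exists because
   first-crossing estimators behave badly on non-monotonic series; with
   it off, the first crossing of a wiggly series is reported as-is.
4. **Crossing.** Scan concentrations low→high for the first crossing of
   the BMR; interpolate linearly in log10(concentration).  A response
   exactly at the BMR yields that tested concentration; a series whose
   lowest tested concentration already exceeds the BMR yields the lowest
   concentration (no extrapolation below the tested range); no crossing
   contributes an "inactive" iteration.
5. **Aggregation.** The reported BMC is the median of finite crossings,
   with 5th/95th percentile limits.  Hit confidence is the fraction of
   iterations with a finite crossing; an estimate is *active* when the
   median is finite, lies within the tested range and hit confidence is
   at least 0.5 (configurable — the cutoff is a convention, not a fitted
   quantity).
6. **Lethality masking.** Animals scored dead contribute only to the
   lethality readout; their behavioral records are excluded before
   summarising, and concentration groups emptied by the mask are dropped
   (flagged).

Known limitation: with essentially noiseless data the bootstrap
distribution collapses onto the deterministic grid crossing, whose
log-linear interpolation on a semi-log grid carries a discretisation
bias of a few percent that differs between curves sampled at different
effective positions.  Interval comparisons then degenerate (two
near-point intervals a few percent apart are "disjoint").  This mirrors
the confidence-interval pathologies published BMC pipelines report for
awkward concentration–response series; realistic animal-level noise
keeps the intervals honest.

## Loewe concentration addition (`mixtox.loewe`)

All BMC-level math is per-component concentration (mixtures are
reported by the concentration of each component); all effect-level
(ICp) math is total-mixture concentration, and every output column is
suffixed accordingly.  The closed forms

    BMC_mix          = 1 / (1/BMC1 + 1/BMC2)           (equimolar, per component)
    BMC_mix          = BMC1 / (1 + RPF2),  RPF2 = BMC1/BMC2
    ICp_mix_total    = 1 / (f1/ICp1 + f2/ICp2)

are exact per effect level for any Hill slopes, because they restate the
linear isobole at that level.  A component with no active BMC is treated
as infinitely dilute (the prediction equals the active component's BMC);
predictions above the 10 µM cap — the top of the tested range — are
flagged and treated as no predicted effect.

**Intervals.** Prediction intervals push the single-agent 5th/95th
bounds through the formula (lower bounds together, upper bounds
together), applying the inactive rule coordinate-wise.  The formula is
monotone in each argument, so the interval contains the point
prediction.  This bounds-through-the-formula rule is a package choice;
the alternative (parametric bootstrap over single-agent BMC
distributions) would propagate distributional shape but requires those
distributions to be stored.

**Predicted curves.** The default `per_level` method recomputes the CA
combination at every effect level from the individual ICp values — the
exact solution.  The `fixed_rpf` shortcut freezes the relative potency
at its IC50 value; it coincides with the exact curve at p = 50 and
everywhere when Hill slopes are equal, and deviates by a bounded,
reported amount otherwise.  Brute-force bisection solvers
(`solve_equimolar_bmc_numeric`, `solve_total_icp_numeric`,
`isobole_inhibition`) provide independent numeric checks of the algebra
(relative bisection tolerance well below 1e-9) and are tested against
the closed forms over 10⁴ random inputs.

## Interaction classification (`mixtox.interactions`)

Interval comparison of observed vs predicted BMCs: overlap → additive;
observed entirely below predicted → synergistic; entirely above →
antagonistic; both inactive → no effect.  When exactly one side is
active the intervals are non-overlapping by rule; an absent BMC behaves
as "beyond the tested range", so an observed-only BMC means the mixture
is more potent than predicted (synergistic) and a predicted-only BMC
means less potent (antagonistic).  Each call records its provenance
(`overlap`/`disjoint`/`one_sided`/`none`), and observed intervals
spanning the full tested range are flagged but still compared
literally.

Overall potency per mixture and worm type is BMC_min — the smallest
active median BMC across readouts and directions — and the discrepancy
statistic log10(BMC_min(predicted)/BMC_min(experimental)); positive
values mean the experimental mixture was more potent than the additive
prediction.  NA propagates when either side has no active BMC.  The
packaged published table stores ratios rounded to two decimals that
were computed from full-precision BMC_min values; recomputing them from
the printed two-decimal columns can legitimately deviate by up to
~0.03, so the replication check tests consistency against the
input-rounding envelope (half a unit in the last printed decimal place
of each input, plus the ratio's own half-ulp) rather than a fixed
absolute tolerance.

## Dose–response fitting (`mixtox.doseresponse`)

Percent-activity data are fit to the two-parameter log-logistic
activity(C) = 100/(1 + (C/IC50)^h) with the asymptotes fixed at 0 and
100% of solvent control.  The fit is nonlinear least squares on
(log IC50, log h) — positivity without bounds — multi-started from five
log-spaced IC50 seeds over the tested range; standard errors come from
the Gauss–Newton curvature at the optimum with the delta method back to
the natural scale.  Replicates enter individually by default
(`aggregate="means"` fits per-concentration means instead).  Activities
outside [0, 100] are retained: the asymptotes are fixed, so clipping
would only bias the fit.  Failures (flat data, optimizer failure, IC50
driven far outside the tested range) return `converged=False`, never an
exception.  Effect levels follow in closed form,
ICp = IC50·(p/(100−p))^(1/h).

## Logit-equivalence additivity test (`mixtox.logit_equivalence`)

Natural-log logits of the inhibition fraction, with inhibition clipped
to [0.5, 99.5]% before the transform (clip events counted and reported;
base and bounds are configurable, and both appear in the output
metadata).  Single agents get OLS lines Y = Y0 + b·log10(C); a
log-logistic curve with Hill slope h has exactly b = h·ln(10), which
serves as the oracle for noiseless fits.  Concentrations of agent A are
converted to B-equivalents through the lines, the expected mixture
inhibition is B's line at log10([A-equivalent] + [B]), and the
regression of observed on expected logits (per-concentration medians by
default) yields a slope whose departure from 1.0 is tested with a
coefficient t-test.  A perfect linear fit returns the exact slope with
a degeneracy flag and p = 1 rather than an error.

**Power caveat.** A pure potency shift multiplies every effective
concentration by a constant, which on the logit scale is an *intercept*
shift — the slope stays 1.  The test gains power against such shifts
only when the inhibition scale saturates within the tested range: the
clipped, flattened top of the observed curve drags the slope below 1.
With steep (Hill ≈ 2) oxon-like curves and a grid reaching 8× the
additive mixture IC50, a 10-fold shift saturates the upper half of the
grid and is detected essentially always; with shallow curves or narrow
ranges the test is blind to potency shifts by construction.  Shape
changes (unequal slopes, concentration-dependent interactions) are what
the statistic is actually sensitive to.

## Synthetic screen generator (`mixtox.simulate`)

The generator emulates the screen's design parameters: 48-well plates
with one animal per well, one row (8 wells) per concentration plus one
row of in-plate solvent controls, three replicate plates (n = 24 per
concentration), concentrations 0.1–10 µM in semi-log steps, adult and
regenerating worm types, days 7 and 12, and triplicate AChE assays.
Every agent follows log-logistic concentration–response curves per
readout; mixtures follow either exact Loewe additivity (per-effect-level
isobole solved numerically by bisection, valid for unequal Hill slopes,
relative tolerance far below 1e-9) or a potency-shift deviation that
divides both components' effective concentrations by a shift factor
(>1 synergy, <1 antagonism), applied to all or a chosen subset of
readouts.  A shift factor of 1 reproduces the additive records exactly
at a fixed seed.

**Noise model (a choice, not a measurement).** Incidence readouts are
per-animal Bernoulli draws from the response probability; continuous
readouts are Gaussian around the expected mean on a raw scale with
control baseline 1.0.  The default continuous noise in the bundled
demonstration screen is SD 0.15 (a 15% per-animal CV) — the low end of
what behavioral readouts show in practice, and enough to keep bootstrap
intervals meaningful (see the BMC limitation above).  Plate/edge
effects are off by default; an additive per-plate offset term exists
for robustness experiments.  No per-readout noise magnitudes were ever
published for the real screen, so none of these values are biological
measurements, and passing tests demonstrate correctness of the
*inference machinery* under the stated noise model, not performance on
real animals.

The demonstration truth (`demo_agent_truth`) uses four adult day-12
readouts spanning both kinds — lethality (EC50 5 µM), stickiness
(3.16 µM), speed decrease (3 µM, max 80%), resting increase (1.5 µM,
max 150%) — all with Hill slope 2 and EC50s placed so that single,
additive-mixture and 10-fold-shifted BMCs stay within the tested range.
The AChE demonstration pair uses IC50s 1 and 13.6 µM (an oxon-like
potency gap) with Hill slope 2; the assay grid spans 1/8× to 8× the CA
mixture IC50 in eight log steps, which keeps the additive mixture's
true inhibition strictly inside the 0.5–99.5% quantifiable band so that
logit observations are free of deterministic clipping — the regime in
which the slope test is calibrated.

**Sham protocol.** The self-mixture validation screens the two
(identical) components independently, exactly as a real pair would be
screened, and builds the CA prediction from the two independent
estimates.  Reusing one single-agent dataset for both components would
artificially correlate the predicted bounds.

## Problem sizes

The validation suite uses the sizes stated above as its study
conditions: 50 replicate screens for the sham/synergy recovery rates
(bootstrap n = 1,000 throughout), 100 simulated assays for IC50
recovery, 1,000 simulations for the slope test's type-I error, 10⁴
random input pairs for the closed-form/solver agreement checks and 10⁴
noiseless points for slope consistency.

## Known limitations

* The BMC estimator is grid-limited: estimates cannot resolve structure
  between tested concentrations, and first-crossing medians carry a
  small noise- and grid-dependent bias (shared by the methods it
  re-implements).
* Interval propagation for CA predictions ignores the correlation
  structure of the bootstrap distributions; it brackets, rather than
  calibrates, the prediction uncertainty.
* The slope-equals-1 test cannot detect pure potency shifts without
  saturation (above), and its calibration assumes the tested range
  avoids deterministic clipping.
* The generator draws readouts independently; real behavioral readouts
  are correlated within animals (a dead-in-all-but-name animal is slow,
  resting and unresponsive at once), so multiplicity across readouts is
  optimistic relative to real screens.
* Equimolar binary mixtures only; no ternary designs, no Bliss
  independence, no response-surface models.
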