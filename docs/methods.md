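# Methods

This note records the statistical model, the numerical choices and the
design decisions behind `bmdkit`, and what the synthetic-data tests do and
do not demonstrate.

## Dose–response model and error structure

Responses are strictly positive continuous measurements (hormone
concentrations, follicle counts, percentages of days in a cycle stage,
organ weights). They are modeled as lognormal around a parametric median
curve: log y ~ Normal(log f(d), σ²) with a single σ across dose groups.
Two consequences worth stating explicitly:

- f(d) is the *median* (geometric mean) of the response distribution, not
  its arithmetic mean. The CES and the BMD are therefore defined on the
  median curve ("central tendency"). A mean-curve parameterization would
  shift f by exp(σ²/2); with σ ≈ 0.1–0.4 the difference is small but not
  zero, and the median convention is used consistently in the likelihood,
  the BMD inversion and the simulator.
- Zero or negative responses are rejected at load time rather than
  offset. Count endpoints are treated as continuous lognormal values;
  the simulator can round them to integers, which at typical counts
  (hundreds) does not perturb the fits. Percentage endpoints (bounded at
  100) are fitted untransformed like every other endpoint; near-boundary
  endpoints would need a transform the package deliberately does not
  apply.

The six mean functions and their parameters are listed in the README.
Conventions:

- `a` is the background; every model satisfies f(0) = a.
- For linear/power/Michaelis–Menten/Hill, the sign of `b` is the response
  direction.
- exp3's sign factor s and exp5's asymptote ratio c cannot encode
  direction through `b` (which is a rate, bounded positive), so both are
  *direction-committed*: s is fixed to the adverse direction of the
  requested CES before fitting, and exp5's c-box is restricted to the
  adverse side ((1, 100] increasing, (0, 1) decreasing). The four
  algebraic models remain free to fit either direction; wrong-direction
  posterior draws simply produce no BMD (see below).

## Priors and internal dose scaling

Priors are independent uniforms over data-scaled boxes — proper by
construction, which bridge-sampling evidence requires, and flat, i.e.
equal prior probability across the plausible range:

| parameter | box | rationale |
|---|---|---|
| a | (0, 100·max y] | contains any plausible background |
| b (algebraic) | [−100·max y, 100·max y] | effect size in response units on the scaled dose axis |
| b (exp3/exp5) | (0, 100] | dimensionless rate on the scaled dose axis |
| c (MM/Hill) | (0, 30] | half-maximal dose up to 30× the top dose |
| c (exp5) | (1, 100] or (0, 1) | asymptote fold-change, direction-committed |
| g | (0, 18] | shape/power, standard BMD-software cap |
| σ | (0, 10] | log-scale SD |

Doses are internally rescaled by the top dose (u = d/d_max) before
fitting, so these boxes are comparable across endpoints whose doses span
four orders of magnitude; reported BMDs are mapped back to natural units.
With flat priors the marginal likelihood depends on the box volumes, so
model weights inherit a volume-sensitivity that any flat-prior Bayesian
model averaging has. One visible consequence: on effectively linear data
the Michaelis–Menten model often takes most of the weight, because its
(b, c) ridge of near-linear curves integrates to more volume than the
penalty for its extra parameter. This is harmless for the averaged BMD —
on that ridge MM's BMD coincides with the linear one — but single-model
weights should be read with this in mind.

## Sampling

Adaptive random-walk Metropolis, one chain by default, 30,000 iterations
with the first 50% discarded as warm-up. Adaptation happens only during
warm-up (a global step size tuned toward ~30% acceptance every 50
iterations; from the second half of warm-up the proposal covariance is
the empirical covariance of the recent history scaled by 2.38²/p). The
proposal is frozen at the end of warm-up, so the retained draws come from
a fixed-kernel chain and detailed balance holds. Everything is driven by
one PCG64 generator: (data, settings, seed) determine the draw matrix
bit-for-bit. Multi-chain runs (optional) report split-R̂.

Starting points are data-driven (background at the control geometric
mean, effect from the top-dose group, σ from pooled within-group log-SD),
which keeps warm-up short; a flat-curve fallback handles starting points
outside the likelihood support. A dataset in which *every* group has zero
variance is rejected as degenerate (σ → 0 blows up the likelihood).

The test/CI profile uses 5,000 iterations (2,500 retained draws); the
conformance suites (evidence oracles, recovery, determinism) pass at that
size, and production runs simply use the default.

## Evidence and model averaging

The marginal likelihood of each model is estimated by iterative bridge
sampling with the optimal bridge function: half the retained draws
moment-match a multivariate-normal proposal, the other half and an equal
number of proposal draws enter the fixed-point iteration, run in log
space with a relative-change stopping rule of 1e-10 (cap 1000
iterations). Proposal draws falling outside the prior box contribute zero
posterior density, which the estimator handles; if more than half do, the
estimate is declared unstable and the model is dropped from the averaging
set with its prior weight renormalized (the event is logged). On
conjugate-normal and quadrature oracles the estimator is accurate to well
under 0.05 log units.

The exponential variant entering the averaging set is whichever of
exp3/exp5 has the higher evidence; exact ties (within 1e-9) resolve to
exp5, a deterministic and documented tie-break. Posterior weights are
w_k ∝ π_k·exp(log ML_k − max), with equal priors (0.2 for the usual
five-model set).

## BMD, credible bounds, clamping

The BMD solves f(d) = f(0)·(1 + direction·magnitude) in closed form for
all six models (the inversions are verified against a bracketing root
finder to 1e-9 relative). A draw whose curve never reaches the target —
wrong direction, or an asymptote short of it — yields NA, as does a
crossing beyond the extrapolation cap of 10⁴ × top dose.

The averaged BMD posterior is built by weight-proportional resampling:
a multinomial allocation of 10,000 resampled draws across models, then
sampling with replacement within each model's BMD draw set, all seeded.
A pooled-weighted-quantile oracle validates the construction in the
tests. NA draws are excluded from the percentiles but counted:
`n_valid_draws` is always reported, more than 50% NA flags the endpoint
as direction-inconsistent (the CES sign disagrees with what the data
support), and fewer than 100 valid draws is an error rather than an
estimate. BMD/BMDL/BMDU are the mixture median and 5th/95th percentiles
(90% credible interval by default); a non-positive BMDL is clamped to 0
and flagged. The reported BMD is the posterior *median*, which is robust
to the heavy right tails that BMD posteriors develop when the curve
flattens; per-model draws and evidences remain inspectable on the results
object.

Reporting rounds doses to 3 significant figures and ratios to 1 decimal;
QC is computed on unrounded values.

## Quality control, ranking, DNEL

QC rejects an estimate when BMDL is 0/NA (ratios undefined), BMD/BMDL >
20, BMDU/BMDL > 50, or BMDL < (lowest nonzero dose)/10; every violated
rule is enumerated in the verdict. Ranking sorts QC-accepted endpoints by
BMDL ascending with BMD as tie-break; failed endpoints follow, flagged.
DNEL = POD × absorption / assessment-factor, reported at 2 significant
figures; defaults (0.7, 100) follow the ECHA DEHP restriction
calculation. NOAEL/LOAEL comparison tables treat sex-specific values as
separate rows sharing a dataset id, and count unique studies by dataset
id; ranges are stored at their lower bound (noted in the fixture
headers).

## Synthetic-data generator

`study_design_suite` emulates the four study designs the analysis was
built around: oral 10-d HPO study (n = 8), oral 10-d organ-weight study
(n = 6), oral 30-d HPO study (n = 8), dietary 30-d HPO study (n = 10,
doses 0.024–240 mg/kg bw/d; the others 0.02–200). Endpoint archetypes
(hormone via Hill/Michaelis–Menten, follicle counts via exp5,
cycle percentages via linear, organ weights via shallow linear/MM) carry
documented true parameters with log-SDs of ~0.4 for hormones, ~0.3 for
counts, ~0.25 for percentages and ~0.1–0.2 for weights, and deliberately
disagree in direction across studies for progesterone and primordial
follicles, mirroring the feedback-driven reversals real studies show.
Noise is multiplicative lognormal only — exactly the analysis's
assumption — with no outliers, dropout or litter effects. Passing
recovery tests on these data therefore shows the estimator is correct
*under its own assumptions*; it says nothing about robustness to
contamination or model misspecification beyond the six-curve family.

Recovery behaviour, as measured by the tests and the acceptance script:
at n = 50/group and log-SD 0.2 the averaged BMD median lands within a
factor of 2 of truth (median over seeded replicates, each of the six
generating models); at the real study sizes (n = 6–10, log-SD up to 0.4)
roughly half the synthetic endpoints recover within a factor of 2 and
several fail QC — wide, partly unreliable intervals are the expected
output at that information level, which is precisely why the QC layer
exists.

## Known limitations

- Flat-box priors make evidences (hence weights) depend on the box
  conventions; alternative bounds give different weights, though the
  averaged BMD is fairly insensitive for curve shapes the data actually
  constrain.
- No hybrid (tail-probability) BMD definition, no dichotomous models,
  no summary-statistics likelihood (group summaries are read but fitting
  requires individual data), no covariates or litter random effects.
- Percent endpoints bounded at 100 are fitted untransformed.
- The sampler is single-threaded; a full four-study suite at production
  settings takes a few minutes on one CPU.
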