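# Methods

## Cost framework

Administration costs are measured from a payer perspective over a fixed
12-month horizon for a single patient completing one continuous treatment
course; there is no discounting and no repeat episode. Every resource item
is attributed to exactly one of two cost centres:

* **proximal (Pc)** — consumed before or after physical administration
  (pharmacy preparation, clinical review, monitoring, consumable disposal);
* **physical (PAc)** — consumed while the drug is introduced via its route
  (infusion-suite occupancy, injection by a nurse, device use).

Items carry a unit cost (GBP, treated as an opaque positive number with no
inflation adjustment) and either a per-administration or a per-year
quantity — never both in one record, so provenance stays unambiguous.
Annual centre totals are `unit_cost × qty_per_admin × DOSFREQ +
unit_cost × qty_per_year`, summed over items.

**Dosing frequency.** DOSFREQ is the number of unit administrations per
year, derived from the licensed interval assuming continuous dosing:
`52/interval` for weekly units, `365/interval` daily, `12/interval`
monthly, capped by any licensed annual maximum, plus any first-year loading
doses, and rounded to 2 decimal places (so three-weekly dosing is 17.33).
The 2-dp rule is a convention of this package chosen so that interval-based
and directly supplied frequencies are interchangeable at the precision used
throughout.

## Monte-Carlo simulation

Parameter uncertainty enters by replacing each deterministic centre cost
with draws from a gamma distribution parameterised shape–scale with shape
α = 1 and scale equal to the deterministic cost, i.e. an exponential whose
mean and SD both equal the cost — the simplest dispersion assumption
available when no empirical variance data exist, and one applied uniformly
so it biases no product relative to another. Pc and PAc are drawn
independently (no correlation structure is assumed); the per-draw total is
their sum. Each product gets its own deterministic substream of the master
seed, so adding a product never perturbs another product's draws.

The **exceedance fraction** — the share of draws with PAc/Pc ≥ 1 —
identifies the dominant cost centre. For independent exponential centres it
has the closed form `pac/(pc+pac)`, which the tests use as an oracle. When
Pc is deterministically zero the ratio is infinite in every draw; the
fraction is then defined as 1.0 and a warning is issued. Distribution
summaries report the third and fourth standardised moments with the
non-excess kurtosis convention (Gaussian = 3), matching the "kurtosis > 3"
heavy-tail rule used in the diagnostics.

A convergence check (`simulation.convergence_check`) re-runs the simulation
at several draw counts and shows the 1/√n shrinkage of the spread of mean
costs; 1000 draws per product is the default working size.

## Estimators

The response of the cost regression is the natural log of the per-product
mean simulated total cost (the mean over draws, not the deterministic value
or a single draw — a modelling choice of this package). The full model (C)
contains the two route dummies (IV omitted), DOSFREQ, the bundling and
indication dummies, DOSFREQ² and DOSFREQ×INDICATN; models A, B and D are
its nested restrictions, compared by the F-ratio
`((SSR_r − SSR_f)/q)/(SSR_f/(n − k_f))`.

* **log-OLS** — via statsmodels OLS; classical and HC1 robust SEs are both
  always computed, and reports label which is displayed. `sigma2_pred` is
  SSR/(n−k), the squared log-scale prediction SE.
* **GLM** — statsmodels IRLS with independently selectable link (identity,
  log, power) and variance family (Gaussian, Poisson, gamma, inverse
  Gaussian); convergence tolerance 1e-8, max 100 iterations; failure to
  converge raises, with no partial result.
* **PGLM/EEE** — authored here (no library implementation exists). The mean
  model uses a Box–Cox link, μ = (1+λη)^(1/λ) with the log-link limit at
  λ = 0; the variance is either quadratic, θ₁μ + θ₂μ², or power, θ₁μ^θ₂.
  Estimation profiles the regression coefficients by damped Fisher scoring
  on the quasi-score at each candidate (λ, θ), while the outer parameters
  maximise the working-normal pseudo-likelihood by Nelder–Mead. The
  solution is a stationary point of the stacked score system (quasi-score
  for β, pseudo-likelihood scores for λ and θ), so sandwich covariance of
  that system gives the confidence intervals, with an n/(n−p) small-sample
  correction. A direct Newton root-finder on the stacked equations was
  evaluated first and abandoned: in finite samples the weighted system
  often has no feasible root, and possesses spurious near-roots along a
  θ₁/θ₂ cancellation ridge; the profiled formulation has neither problem.
  The response is internally divided by its geometric mean (the Box–Cox
  link family is closed under scaling, so the solution back-transforms
  exactly) to make the optimisation invariant to the currency unit.
  Non-convergence — including the outer optimiser exhausting its evaluation
  budget on the very flat λ ridge that an 18-observation, 11-parameter fit
  produces — is reported through `converged=False` with a message, never
  raised, because a failed EEE fit is itself a reportable analysis outcome.
  Fixing λ = 0 and θ₂ = 0 makes the quasi-score independent of θ₁ and
  exactly reproduces a log-link Poisson GLM, which the tests exploit as an
  equivalence oracle.

**Diagnostics.** The modified Park test regresses squared raw-scale
residuals on ln(fitted) with a log-link gamma GLM; the slope estimates the
over-dispersion exponent δ in var ∝ mean^δ, Wald-tested against 0/1/2/3 to
suggest a family (failing to reject all four is a legal outcome on small
samples). Pregibon's link test refits the response on the linear predictor
and its square; the modified Hosmer–Lemeshow test F-tests group-mean
residuals across fitted-value quantiles, defaulting to min(10, n/3) groups
because 18 observations cannot support 10 groups; Breusch–Pagan (LM form)
and a standard Park auxiliary regression of exp(residual) on the regressors
probe heteroskedasticity; residual shape reports skewness, non-excess
kurtosis, a D'Agostino normality test and the leptokurtosis flag; DFFITS
influence uses the threshold 2√(p/n) (1.333 at p = 8, n = 18), with a
second flag at twice the threshold.

## Retransformation

Exponentiating fitted log costs estimates the geometric, not arithmetic,
mean; four smearing factors correct this: normal-theory exp(σ̂²/2), Duan's
mean of exp(residual), route-subgroup Duan factors, and Wooldridge's
through-the-origin slope of y on exp(fitted). Selection scores each method
by the squared Pearson correlation between smeared predictions and the
observed raw response; ties (within 1e-6) resolve to the subgroup method,
which supports formulation-specific prediction. Prediction for a scenario
uses the factor of its route, falling back to the overall Duan factor (with
a warning) when the route subgroup is absent.

## Prediction algorithm

`predict_ln_cost` evaluates the model-C linear index for a scenario;
`predict_cost` multiplies exp(index) by the chosen smearing factor.
Coefficients are stored signed throughout; effect formulas written with
magnitudes elsewhere are reproduced exactly by the signed algebra.
Incremental effects of dummies use Kennedy's small-sample correction
100·[exp(β − SE(β)²/2) − 1] (the uncorrected 100·[exp(β) − 1] is available
as `method="simple"`); marginal effects of dosing frequency are the
analytic derivative 100·(β₂ + 2β₅f + β₆·INDICATN); the turning point is
(β₂ + β₆·INDICATN)/(−2β₅), undefined (returned as None) when β₅ ≥ 0.
Route-switch savings are reported per patient and per cohort; negative
savings are cost increases and are reported as such.

## Synthetic data generator

The generator emulates the structure of the study sample the estimators
are designed for: 18 products — 8 IV, 8 SC, 2 IM — with two acute
indications placed in the IV and IM groups only (no SC product is acute),
every SC/IM product bundled, and a fixed quarter of IV products bundled
(keeping bundling linearly independent of the route dummies, as in the
real sample). Dosing frequencies are uniform over route-typical ranges
(IV 4–26, SC 12–156, IM 6–365 per year). Per-administration costs are
log-normal around route-typical medians chosen so IV products carry a
larger physical-cost share (IV: Pc ≈ £150, PAc ≈ £250 per administration;
SC: £25/£8; IM: £20/£10; log-SD 0.5), chronic products add a small annual
review item, and totals are clipped to a configurable £35–£19,000 band.
These magnitudes are configuration, not constants, and are realistic for
UK hospital settings in order of magnitude only.

What the generator does **not** emulate: the real per-product line-item
costs (the deposited appendices are unavailable), correlation between Pc
and PAc, dose banding or vial sharing, routine-practice deviations from
licensed posology, and price-year effects. Tests passing on synthetic data
therefore demonstrate the correctness of the machinery — estimators,
retransformation, prediction arithmetic — not the reproduction of the
study's per-product cost levels, which is explicitly out of scope.

`generate_from_model` draws responses directly from the cost model
(ln cost = linear index + Normal(0, σ) noise, default σ = 0.84, the
log-scale prediction SE of the full-model fit) for parameter-recovery and
retransformation-bias experiments.

Packaged fixtures carry the published constants at printed precision — the
18-product roster, the nested-model and alternative-estimator coefficient
tables, the smearing factors, and the IV→SC reformulation worked example —
for desk-scale checks and prediction-only use. The published IV subgroup
factor appears in two inconsistent versions (1.0206 in the validation
summary, 1.0792 in the worked example); the sources cannot be reconciled,
so smearing factors are explicit inputs to prediction and the
worked-example fixture pins 1.0792.

## Numerical choices and problem sizes

* GLM convergence: deviance tolerance 1e-8, 100 iterations. EEE: outer
  Nelder–Mead xatol 1e-6 / fatol 1e-8, ≤600 iterations; inner Fisher
  scoring tolerance 1e-10; λ constrained to |λ| ≤ 5.
* Significance levels 1/5/10% with no multiple-testing correction.
* Degenerate inputs: constant responses are rejected by the EEE; zero
  residual vectors short-circuit the link, pattern and heteroskedasticity
  tests to a zero statistic; a deterministic zero proximal cost defines
  exceedance as 1.0 with a warning.
* Replication experiments run at: 200 replications for Park/link/pattern
  test calibration (n = 200 each), 500 replications of the 18-product
  design for coefficient CI coverage, 100 replications of n = 500 for the
  EEE λ coverage check, and 10⁵ draws for distributional oracles. These
  sizes give stable Monte-Carlo verdicts while keeping the default suite
  around half a minute.

## Known limitations

* The EEE's power-variance family converges less reliably than the
  quadratic family, especially at n = 18; this mirrors the behaviour of
  flexible-link estimators on small samples generally, and the failure is
  reported, not hidden.
* Wald CIs for λ undercover slightly below n ≈ 300 (≈86% at n = 150);
  profile-likelihood intervals would improve this and are not implemented.
* Predictions carry no confidence intervals (point predictions only).
* Acquisition-cost trade-offs, cost-effectiveness modelling and
  non-monetary administration attributes (needle phobia, compliance) are
  out of scope.
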