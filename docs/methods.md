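# Methods

## The censoring model

An assay converts a true concentration y* into a reported value in three
stages: a noisy readout, a calibration map, and a reliability screen. We
model the readout as multiplicatively noisy,

    y = y* · (1 + CV(y*) · ε),   ε ~ N(0, 1),

so the relative error SD at concentration y* equals the assay's coefficient
of variation there. The CV curve is parametrised as

    CV(x) = cv_base + k_low / x + k_high · x,

the simplest three-parameter family with the empirically ubiquitous U shape:
a hyperbolic rise at low concentrations (signal approaching background
noise), a linear rise at high concentrations (saturation), and a floor of
`cv_base` in between. An empirical alternative (`fit_precision_profile`)
estimates the three coefficients from calibrator replicates by nonnegative
least squares on the basis (1, 1/x, x).

The quantification limits LLOQ/ULOQ are the concentrations where CV(x)
crosses the acceptance cutoff (default 10%); they are located by Brent root
bracketing to relative tolerance 1e-9 between the CV minimum and the range
ends. If the CV never exceeds the cutoff on the range, the limits collapse
onto the range bounds and are flagged (`no_finite_limits`).

Censoring is applied to the *measured* value, not the true one — a
laboratory can only compare its readout to the cutoffs. The convention is
strict: `y < LC` is BC, `y > UC` is AC, equality stays observed. A value
driven nonpositive by noise is redrawn (at most 100 rounds, then an error);
concentrations are positive by definition.

Censored records are **missing not at random**: the event "no number
reported" is informative about the magnitude. This is why the package offers
no overall-mean or overall-median imputation — under MNAR those are biased by
construction.

## Censored-lognormal maximum likelihood

Biomarker concentration distributions are right-skewed and positive; the
lognormal LN(meanlog, sdlog) is the assumed generating family. The censored
log-likelihood

    l(μ, σ) = Σ_obs log f(y_i) + n_BC log F(LC) + n_AC log(1 − F(UC))

is maximised over (μ, log σ) — the log transform keeps the search
unconstrained — by Nelder–Mead with objective tolerance 1e-8, initialised at
the mean and (n-denominator) SD of the log observed values. With no censored
records the optimum coincides with the closed-form lognormal MLE, which the
tests assert to 1e-6. The observed-value term is evaluated through sufficient
statistics (n, Σ log y, Σ (log y)²), making each objective evaluation O(1)
in n.

Numerical guards and diagnostics:

* A censored interval with zero probability mass contributes −1e10 per
  record instead of −∞, keeping the objective finite for the optimizer.
* Convergence requires both optimizer success and a gradient norm below
  1e-5 · max(1, n) — the likelihood scales with n, so a fixed absolute
  tolerance would misclassify large-sample fits. Non-convergence is returned
  as a flagged result with a warning, never silently.
* Standard errors come from the numerically inverted observed information in
  (μ, σ), central differences with relative step 1e-5. They are diagnostics;
  imputation does not use them.
* A fit requires at least 3 observed values; below that the two-parameter
  model is practically unidentifiable and the fit raises rather than
  producing a degenerate imputation basis.

Truncated-tail sampling is by inverse CDF: `x = Q(F(a) + u·(F(b) − F(a)))`
with u uniform, which handles a = 0 (F = 0) and b = ∞ (F = 1) exactly and is
reproducible from the seed. Draws are nudged off the interval endpoints by
one ulp so the open-interval contract holds even for tiny-mass intervals.

## Handling methods

Deterministic methods (deletion; range-extreme, interval-midpoint and
cutoff-value imputation) are forced to m = 1. The distribution-based methods
default to **m = 10** imputations — enough to stabilise the averaged
criteria at negligible cost; single imputation understates between-imputation
uncertainty and is deliberately not the default. The BC interval lower bound
is 0 (a concentration cannot be negative); the AC interval needs the
measurement-range maximum for `M_fix1`, `M_fix2` and `M_uni`, while `M_log`
samples the fitted upper tail to ∞ and needs no such bound. `M_log` fits once
per dataset and draws all m imputations from that fit; refitting per
imputation would only add optimizer noise, since the fit uses no randomness.

Rubin's rules are provided for pooling per-imputation estimates
(Q̄ = mean, T = W + (1 + 1/m)·B). The simulation study itself averages the
point criteria across the m completed datasets rather than Rubin-pooling,
because its criteria are descriptive deviations, not inferential estimates
with per-imputation variances.

## Evaluation criteria

Per run, each completed dataset is compared with the **true simulated sample
of the same run** (not the theoretical distribution): percent deviation of
mean, SD (n−1 denominator) and median, plus the two-sample
Kolmogorov–Smirnov distance, evaluated exactly over the pooled jump points.
Using the sample as reference keeps deviations well-defined for deletion
(whose completed dataset is shorter) and isolates the handling method's
error from ordinary sampling noise. The two-sample KS form was chosen for
the same reason — it needs no distributional reference and handles unequal
lengths. Aggregation over runs or grid cells is the arithmetic mean per
criterion; the `mse_*` columns are means of squared per-cell averages, used
to rank methods over the cutoff sweep.

A structural consequence worth knowing: all BC-imputed values are ≤ LC ≤
every observed value, and all AC-imputed values ≥ UC, so whenever both
censored fractions are below 50% the completed-dataset median is the same
order statistic of the observed block for *every* imputation method — median
deviations only separate the methods in extreme censoring regimes.

## Simulation study design

Shipped scenarios all use meanlog = ln 100 ≈ 4.6052; cutoffs are the
lognormal quantiles matching each scenario's target censored pattern,
rounded to one decimal:

| scenario | sdlog | LC | UC | target BC/AC |
|----------|-------|------|-------|--------------|
| A | 0.5 | 72.5 | 279.2 | 26% / 2% |
| B | 0.5 | 31.3 | 137.9 | 1% / 26% |
| C | 1.0 | 92.8 | 232.0 | 47% / 20% |
| D | 0.5 | 35.8 | 279.2 | 2% / 2% |

Defaults: n = 1000 records per dataset and 50 runs per scenario — n large
enough for stable medians and censored fractions, 50 runs enough that
averaged criteria move by well under the effect sizes of interest. The noise
profile default (cv_base = 0.04, k_low = 1.0, k_high = 0.0002, i.e. CV
≈ 5–10% near the cutoffs) represents a well-validated assay worked near its
limits. The measurement range default is [0, 400]: an upper range limit
comfortably above the largest cutoff considered, as a lab would configure
calibrators to cover the expected concentrations. All of these are
config-exposed.

The cutoff sweep varies LC and UC over [30, 300] in steps of 10, keeping
cells with UC − LC ≥ 40 (300 admissible cells), at 10 runs per cell — the
step and replication give smooth bias maps at desk scale while keeping a
full sweep under a minute. Per-cell seeds are derived deterministically from
(master seed, cell indices) via `numpy.random.SeedSequence`, so any cell is
reproducible in isolation and sweeps parallelise trivially.

Expected qualitative structure, asserted by the acceptance tests: deletion
and cutoff-value imputation (`M_del`, `M_fix3`) shrink the SD everywhere and
bias the mean *toward* the surviving tail (up when censoring is mostly BC,
down when mostly AC); range-extreme imputation (`M_fix1`) inflates the SD and
biases the mean the opposite way; the fitted-distribution method (`M_log`)
attains the smallest KS distance in every scenario and the smallest
mean-deviation MSE over the sweep.

## What the generator does and does not emulate

It emulates: lognormal true concentrations, concentration-dependent relative
measurement error, and hard cutoff censoring with only counts retained for
censored records. It does **not** emulate assay drift, plate/batch effects,
nonlinear (4PL) calibration, covariate-dependent cutoffs, repeated measures,
or a *misspecified* generating family — every simulated dataset really is
lognormal. Passing benchmarks therefore demonstrate correct behaviour when
the lognormal assumption holds; they say nothing about robustness when the
true distribution is heavier- or lighter-tailed, which remains the user's
modelling judgement (the fit interface is family-agnostic to allow such
extensions, but only the lognormal is implemented).

## Known limitations

* Univariate only. With multiple correlated biomarkers or covariates, a
  censored regression (Tobit-type) model or multivariate imputation is the
  appropriate tool; neither is implemented here.
* The censored MLE needs a reasonable number of observed values; with very
  extreme censoring (e.g. > 90% on one side) the fit can converge to the
  boundary of usefulness, and the per-run failure handling in the study
  runner excludes such runs with a warning.
* Reported standard errors are asymptotic (observed information); no
  bootstrap alternative is provided.
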