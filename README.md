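# censimpute

Tools for handling **non-detectable and out-of-range values in univariate
biomarker data** — concentrations an assay reports only as "below the lower
cutoff" (BC, e.g. below the lower limit of quantification) or "above the
upper cutoff" (AC, e.g. beyond the upper limit). Such records are *censored*,
not missing at random: their absence itself signals a genuinely low or high
concentration, so deleting them or plugging in observed-data summaries biases
every downstream estimate.

The package is aimed at researchers analysing assay data (hormone
concentrations, clinical chemistry, any LC-MS/MS-style readout) who need to
(a) understand where their quantification limits come from, (b) complete a
censored dataset defensibly, and (c) see how much damage the common shortcuts
do.

## What it provides

**Measurement model.** Linear calibration fitting, a parametric coefficient-
of-variation (CV) precision profile `CV(x) = cv_base + k_low/x + k_high·x`,
derivation of the LLOQ/ULOQ as the concentrations where the CV crosses an
acceptance cutoff (10% by default), multiplicative measurement noise, and
cutoff censoring. Records with measured value `y < LC` become BC, `y > UC`
become AC; only observed values inside `[LC, UC]` keep a number.

**Censored-lognormal fitting.** The core estimator maximises

```
l(μ, σ) = Σ_obs log f(y_i; μ, σ) + n_BC · log F(LC; μ, σ) + n_AC · log(1 − F(UC; μ, σ))
```

where `f`/`F` are the lognormal pdf/CDF — the observed values plus the
*counts* of censored records and the cutoffs identify the full, uncensored
generating distribution.

**Six handling methods.**

| method | BC records → | AC records → |
|--------|--------------|--------------|
| `M_del`  | deleted | deleted |
| `M_fix1` | measurement-range minimum | measurement-range maximum |
| `M_fix2` | LC/2 | (UC + range max)/2 |
| `M_fix3` | LC | UC |
| `M_uni`  | Uniform(0, LC) draws | Uniform(UC, range max) draws |
| `M_log`  | fitted lognormal truncated to (0, LC) | fitted lognormal truncated to (UC, ∞) |

`M_uni` and `M_log` are multiple-imputation methods (default m = 10);
per-imputation estimates can be pooled with Rubin's rules
(`T = W + (1 + 1/m)·B`).

**Benchmarking.** Four shipped scenarios with distinct censoring patterns
(26%/2%, 1%/26%, 47%/20%, 2%/2% BC/AC) and a systematic sweep of both cutoffs
over [30, 300] evaluate every method by the percent deviation of mean, SD and
median from the true sample and by the two-sample Kolmogorov–Smirnov
distance.

## Worked example

```python
import numpy as np
from censimpute import (
    PrecisionProfile, MeasurementRange, MethodSpec,
    measure, censor, fit_censored_lognormal, impute_dataset,
    evaluate_reconstruction,
)

rng = np.random.default_rng(42)
truth = rng.lognormal(mean=np.log(100), sigma=0.5, size=1000)  # true concentrations
assay = PrecisionProfile(cv_base=0.04, k_low=1.0, k_high=0.0002)
measured = measure(truth, assay, seed=rng)                      # noisy readout
data = censor(measured, lc=72.5, uc=279.2, true_values=truth)

fit = fit_censored_lognormal(data)
completed = impute_dataset(
    data, MethodSpec(method="M_log", m=10, seed=7, range=MeasurementRange(0, 400))
)
print(evaluate_reconstruction(truth, completed))
```

With this seed the censored dataset has 268 BC (26.8%) and 14 AC (1.4%)
records out of 1000. The censored fit recovers `meanlog = 4.5881
(SE 0.0162)` and `sdlog = 0.4852 (SE 0.0137)` — the truth (`ln 100 ≈ 4.6052`,
`0.5`) within about one standard error, despite 28% of the records carrying
no value. The reconstruction comparison prints:

```
M_log:  ΔMean = -0.51%  ΔSD = -1.31%  ΔMedian = -1.23%  d_KS = 0.024
M_del:  ΔMean = +13.90%  ΔSD = -23.09%  ΔMedian = +14.96%  d_KS = 0.264
```

Deleting the censored records (here mostly low values) inflates the mean and
median by ~14–15% and shrinks the SD by 23%, while imputing from the fitted
truncated distribution reconstructs all three statistics to about a percent
and brings the KS distance down by an order of magnitude.

## Command line

```bash
censimpute impute --input data.csv --lc 72.5 --uc 279.2 --method M_log --m 10 \
    --seed 1 --output imputed.csv
censimpute loq --calibrators calibrators.csv --cv-cutoff 0.10
censimpute simulate-scenario --name A --seed 1 --outdir results/
censimpute simulate-grid --seed 1 --outdir results/
censimpute evaluate --true-values true.csv --imputed imputed.csv --output metrics.csv
```

Input CSVs use explicit status flags (`sample_id,value,status` with status
`OBS`/`BC`/`AC`; no `<LLOQ` sentinels), and every output embeds the seed and a
config hash in `#` header lines.

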