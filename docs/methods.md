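# Methods

`scanprof` implements a risk-adjusted evaluation of inpatient CT-scan
utilization: encounter-level scan counts are modeled as a function of
clinical risk factors, the best-fitting count model supplies each
encounter's expected number of scans, and each patient group (MDC-style
major diagnostic category) is judged by the ratio of its observed to
expected scan totals. This note records the models, the defaults, the
numerical choices, and what the synthetic cohorts do and do not show.

## Count models

Let `y_i` be the scan count of encounter `i`, `x_i` its covariate row
(intercept; sex; age; admission condition; first-time hospitalization;
critical/serious condition; insurance; complication/comorbidity grade;
admission method; length of stay; surgery count; case-mix index — dummy
coding against the references female / dangerous / no / no / yes / none /
outpatient, continuous covariates linear and untransformed). Four
families are fitted by maximum likelihood:

* **Poisson** — `y ~ Pois(mu)`, `log mu = x' beta`.
* **Negative binomial (NB2)** — variance `mu + alpha mu^2`; `alpha -> 0`
  recovers Poisson.
* **ZIP / ZINB** — a structural-zero state with probability
  `pi = expit(z' gamma)` mixed with the Poisson / NB2 count process:
  `P(0) = pi + (1-pi) f(0)`, `P(y>0) = (1-pi) f(y)`. Both parts use the
  full covariate list by default (configurable per part).

Expected scans per encounter are `mu` (Poisson/NB) or `(1-pi) mu`
(ZIP/ZINB). The zero part is reported as odds ratios `exp(gamma)`, the
count part as incidence rate ratios `exp(beta)`, both with Wald CIs from
the observed information (central-difference Hessian of the
log-likelihood at the optimum, dispersion differentiated on the natural
`alpha` scale).

### Fitting

The packed parameter vector `(beta, gamma, log alpha)` is maximized with
L-BFGS-B using exact analytic scores. Two numerical choices matter:

* **Preconditioning.** The optimizer works on the coefficients of the
  centered-and-scaled design (affine reparameterization; estimates are
  mapped back exactly). Raw clinical covariates (age ~ 57 ± 16, LOS ~ 9
  days) otherwise correlate so strongly with the intercept that
  quasi-Newton steps stall short of the gradient tolerance.
* **Dispersion floor.** `alpha` is optimized as `log alpha` with a floor
  of 1e-8. Below that the NB2 pmf is evaluated as its exact Poisson
  limit: at `r = 1/alpha ~ 1e10` the `lgamma(y+r) - lgamma(r)` difference
  loses more precision (~1e-5) than the limit approximation gives up
  (~1e-8).

Convergence means max |mean score| < 1e-5 (or the dispersion resting on
its Poisson floor); the flag is honest — non-convergent fits are
returned flagged and refused by downstream prediction. Warm starts:
count part from an internal Poisson fit, zero part from a logistic fit
of the zero indicator, `alpha` from method of moments; bootstrap refits
start from the full-data optimum.

## Diagnostics

* **Overdispersion O test** — `O = sqrt((n-1)/2) (s^2/ybar - 1)`, the
  standardized dispersion index, asymptotically N(0,1) under Poisson
  equidispersion; `O >= 1.96` flags overdispersion. The statistic is a
  strategy hook, so an alternative dispersion statistic can be swapped
  in without touching the decision logic.
* **Vuong test** — `Z = sqrt(n) mean(m) / sd(m)` with `m_i` the
  per-encounter log-likelihood difference between the zero-inflated
  model and its plain counterpart (ZINB vs NB by default; ZIP vs
  Poisson available); `Z >= 1.96` prefers the zero-inflated model.
  AIC- and BIC-corrected variants subtract the parameter-count penalty
  from `mean(m)`.

  *Caveat*: when the data truly carry no zero inflation the uncorrected
  statistic is badly oversized as a test of zero inflation — in our null
  simulations it crossed 1.96 in over 90% of replicates, a known
  consequence of the inflation parameter sitting on its boundary under
  the null. The AIC-corrected variant was correctly calibrated (0%
  rejections). The uncorrected form remains the default because it is
  the classical statistic this kind of study reports; its positive
  verdict should be read as "the zero-inflated fit is closer", not as a
  calibrated hypothesis test.

## O/E profiling and classification

For each group `g`: `O_g = sum y_i`, `E_g = sum Ehat[Y|x_i]` from the
selected model (fitted to the pooled study sample without group
indicators — required, since group indicators would force `O = E` per
group). The ratio `O_g/E_g` is the indirect-standardization statistic;
classification is by its 95% CI: entirely above 1 = over-scanning,
entirely below 1 = under-scanning, containing 1 = rational.

**Wald interval.** The classical SMR-style interval uses
`Var(log O/E) = 1/O` (expected treated as fixed), which is exact only if
counts are Poisson. The package's default instead plugs in the selected
model's own variance: `Var(log O/E) = sum_i Vhat(y_i) / O^2`, with
`Vhat = mu`, `mu(1+alpha mu)`, `(1-pi)mu(1+pi mu)` or
`(1-pi)mu(1+alpha mu+pi mu)` per family. For a Poisson fit this reduces
to `E/O^2 ~ 1/O`, i.e. the classical interval is the Poisson special
case. The motivation is coherence: the pipeline selects an overdispersed
model precisely because variance exceeds the mean, and a Poisson-variance
interval then under-covers — in simulation it mislabeled about a quarter
of truly rational groups, while the model-based interval restored ~95%
coverage without costing any power against 1.5x / 0.7x distortions. The
classical form stays available (`variance="poisson"`, and the bare
`wald_ci(O, E)` helper). A zero observed total gets lower bound 0 and a
continuity-corrected upper bound evaluated at O + 0.5.

**Bootstrap.** Internal validation resamples whole encounters with
replacement, refits the model, and recomputes every group ratio; the
percentile interval therefore carries model as well as sampling
uncertainty. Non-convergent resamples are redrawn (aborting if more than
10% of B fail); groups absent from a resample simply contribute no value
there, with per-group replicate counts reported. Default B = 1,000;
tests and the acceptance script use B = 200 for desk-scale runtime.
Classification uses the Wald interval; a config switch allows
classifying on the bootstrap interval instead.

Note the ten groups are classified by unadjusted 95% intervals, with no
multiplicity correction — deliberate, to mirror standard profiling
practice, and flagged here as a caveat.

## Pipeline

`run_pipeline` chains: exclusion filters (drop encounters with total
cost strictly outside the 1st–99th percentile of the input distribution,
linear-interpolation percentiles, ties at the bounds kept; drop stays
over 60 days, a stay of exactly 60 kept) → top-k groups by observed scan
totals (ties lexicographic) → O and Vuong diagnostics → all candidate
fits → goodness-of-fit table → selection (lowest AIC by default; BIC
disagreement is recorded in the diagnostics) → coefficient table →
group evaluation → descriptive tables (categoricals as count (%),
continuous as mean ± SD when |skewness| <= 1, else median (P25, P75)).
All randomness flows from one root seed through per-stage derived
streams; reruns with the same config are byte-identical.

## Synthetic cohorts

The generator emulates a one-year inpatient cohort of a large tertiary
hospital: ten MDC-style groups with uneven prevalence (from ~0.5% to
~22%), eleven covariates with realistic marginals (45.7% female; age ~
N(57.5, 15.9) truncated to [0, 110]; 2.3% dangerous / 29.5% urgent
admissions; LOS log-normal with median 7 d; CMI log-normal with median
0.90, truncated at 12 because DRG relative weights are bounded in
practice; surgery count Poisson(1.7)). Two groups (pre-grouped
procedures, polytrauma) carry heavier case mix via longer stays, higher
CMI and more procedures. Counts are ZINB with `alpha = 0.30`, a ~25%
structural-zero share (overall zero fraction ~44%; the real cohort's
zero share is not published, so this is a package calibration), and a
cohort mean of ~1.28 scans per encounter.

Each group's count-part mean is multiplied by a distortion `delta_g`
(the planted ground truth): the defaults plant five over-scanning
groups (1.10–1.48), three under-scanning (0.72–0.90) and two rational
(1.00), echoing the qualitative pattern such evaluations report. `delta`
multiplies the count mean only, not the zero probability, so the planted
effect is unambiguously a rate distortion.

What passing tests show: the estimator recovers its own generative
parameters, model selection finds the true family, and O/E profiling
recovers planted rate distortions when the risk model is correctly
specified and distortions offset across the cohort. What they do not
show: robustness to unmeasured confounding, reverse causality (LOS is
both covariate and plausibly a consequence of scanning), miscoded
covariates, or within-group covariate-mix differences beyond those
simulated — on real data the O/E verdicts inherit every defect of the
risk model.

## Experiment scales

Simulation-based checks use cohort sizes chosen to keep the full suite
at desk scale while leaving comfortable statistical margins: oracle
equivalence at n = 5,000; parameter recovery, 50 cohorts of n = 20,000;
model-selection fidelity, 50 cohorts of n = 10,000; O-test calibration,
500 cohorts of n = 5,000; Vuong power, 20 cohorts of n = 20,000 at a
planted ~30% structural-zero share; classification recovery, 50 cohorts
of eight groups x 3,000 encounters with offsetting deltas
{1.5, 0.7, 0.8, 1.0 x 5}.

## Known limitations

* The pooled risk model identifies only *relative* deviation: a
  distortion common to all groups is absorbed into the coefficients and
  invisible to O/E profiling. The planted-distortion experiments
  therefore balance deltas to mean 1; with unbalanced distortion the
  rational/over/under boundary shifts by the cohort-average distortion.
* Zero-part coefficients with rare reference cells (the ~2.3%
  "dangerous" admission stratum) are weakly identified; their sampling
  SD at n = 20,000 is ~0.2 and small finite-sample biases are visible in
  recovery experiments, shrinking as O(1/n).
* The Vuong default is uncalibrated at the no-inflation boundary (see
  above).
* No hurdle models, random effects, covariate selection, funnel-plot
  control limits or multiplicity adjustment.
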