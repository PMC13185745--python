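# Methods

This note documents the statistical models the package implements, the
defaults it ships, the design choices that were genuinely open, and what the
synthetic data can and cannot show about a real trial.

## 1. Priors from published summaries

A historical trial reports a ratio effect $\hat\theta$ (rate ratio or hazard
ratio) with a $100(1-\alpha)\%$ confidence interval $(L, U)$. We assume the
interval is Wald-type on the log scale — the standard construction for
published HR/RR intervals — so the standard error is

$$s = \frac{\ln U - \ln L}{2 z_{1-\alpha/2}}, \qquad z_{0.975} = 1.959964.$$

The **downweighted prior** is $N(\ln\hat\theta, (k s)^2)$ with inflation
factor $k = 2$ by default: doubling the SD quarters the information,
discounting the historical evidence by half per the usual
variance-inflation convention. The $N(a, b)$ notation throughout reads $b$
as a **standard deviation**, the only reading under which doubling the SD
and the published benefit probabilities (82%, 87%, 92% for the three
historical sources) are mutually consistent. One inconsistency in the
source table is worth flagging: the third historical row prints an SD of
0.10, but the stated doubling rule applied to its CI gives 0.141 — and only
0.141 reproduces that row's printed 92% benefit probability. The package
follows the rule, not the printed SD.

**Prior probability of benefit** is the log-normal CDF
$P(\theta < t) = \Phi\!\big(\tfrac{\ln t - \mu}{\sigma}\big)$, weight-averaged
for mixtures.

### Meta-analytic predictive (MAP) prior

Downweighted study summaries $y_i \pm s_i$ are pooled with the
normal-normal hierarchical model

$$y_i \sim N(\theta_i, s_i^2), \quad \theta_i \sim N(\mu, \tau^2), \quad
\mu \sim N(0, 10^2), \quad \tau \sim \text{half-}N(0, 0.5),$$

and the MAP prior is the predictive distribution of a new study's effect
$\theta_{\text{new}} = \mu + \tau\varepsilon$. The half-normal(0.5) scale is a
weakly-informative default for a between-study SD on a log-ratio scale (the
source analysis does not state its hyperprior); it is exposed in
`MapModelConfig.tau_prior_scale`. Because $\mu$ is conjugate given $\tau$,
the implementation marginalizes $\mu$ analytically, samples only
$\log\tau$ by MCMC (with an R-hat > 1.01 check that raises), draws
$\mu \mid \tau$ exactly, and computes the moment-matched normal summary by
deterministic quadrature over the one-dimensional $\tau$ posterior — so the
reported moments carry essentially no Monte Carlo error and match a 2-D
grid-integration oracle to ~1e-3.

**Robustification** mixes in a vague component:
$\pi = (1-w)\,N(m_{\text{MAP}}, s_{\text{MAP}}^2) + w\,N(0, 0.5)$ with
$w = 0.10$. With two moderately heterogeneous studies and the half-normal(0.5)
hyperprior the predictive SD (~0.45) is wider than the single normal the
source analysis prints (0.20); since neither its hyperprior nor its
mixture-summarization rule is published, the printed MAP row is treated as
a qualitative, not exact, reference. Both the raw mixture and the
moment-matched normal (law of total variance) are emitted.

The vague prior is $N(0, 0.5)$ (SD 0.5, giving a 50% prior probability of
benefit); it is also the default treatment prior of every model.

## 2. Synthetic trial generator

Per patient: a stratum (4 regions × 2 LVEF groups, default cell
probabilities 0.30/0.25/0.25/0.20 × ½), a gamma frailty
$u \sim \Gamma(\phi, \phi)$ (mean 1, variance $1/\phi$), an administrative
censoring time uniform on
$[T_{\max} - \text{spread},\, T_{\max}]$ (staggered accrual, common end
date), exponential cardiovascular and other-cause death times, and a
homogeneous Poisson process of HF events with intensity
$u\,\lambda_0 e^{\beta\cdot\text{active}}$ over the realized follow-up.
Marginal counts at fixed follow-up are therefore negative binomial with
dispersion $1/\phi$ (verified by a chi-square goodness-of-fit test at
n = 10⁴), and $\phi \to \infty$ recovers the Poisson limit.

Defaults describe the study conditions the package targets: 3000 patients
per arm, $\beta = \ln 0.84$, placebo HF intensity 0.20/person-year plus CV
death 0.032 and non-CV death 0.028/person-year (a composite event rate in
the low 20s per 100 person-years), death HR 0.93, frailty shape 1,
$T_{\max} = 3.4$ years with a 1.5-year accrual spread (median follow-up
≈ 2.65 years ≈ 32 months). Safety flags are independent per-arm Bernoulli
draws whose default probabilities mirror the reported pattern
(hyperkalaemia 7.1% → 14.6%, hypokalaemia roughly halved, modest excesses
of hypotension and creatinine rise, balanced serious adverse events); the
placebo rates for the flags without a published placebo value are plausible
choices, not published numbers.

By default the frailty also scales both death intensities
(`shared_frailty_death`), inducing the positive association between event
burden and death that a composite analysis implicitly assumes; the real
trial's joint distribution is unknown, so this is a declared modelling
assumption, not a claim about any particular dataset.

Randomness is keyed per patient — `default_rng([seed, arm, index])` — so
enlarging an arm never reshuffles previously generated patients, and a
fixed configuration is bit-reproducible.

**Calibration to printed margins** (`calibrate_to_margins`) solves for
(baseline rate, log rate ratio, frailty shape, maximum follow-up) by least
squares so that the *expected* per-arm total composite events, patients
with ≥1 event, and the median follow-up match published counts. The
expectations are computed semi-analytically: closed forms conditional on
frailty and censoring time, integrated by gamma-quantile and uniform
midpoint quadrature (64 × 32 nodes). Event totals and follow-up carry 20×
the weight of the with-event counts, because the rate-ratio estimand
depends on events per person-year while the with-event margin only
identifies the overdispersion; a single shared frailty shape cannot match
both arms' with-event counts exactly (they disagree by ~2% at the printed
margins), which is the known residual of this calibration.

## 3. Likelihoods

All models share: treatment effect $\beta$ on the log scale with the
configured prior (normal or mixture, the mixture evaluated natively in the
posterior so robust-MAP behaviour under prior-data conflict is preserved);
$N(0, 5)$ priors on intercepts, strata effects and log baseline segments;
Exponential(1) on the negative binomial overdispersion $\kappa$ (sampled as
$\log\kappa$ with the Jacobian). Strata enter as fixed effects of the
region × LVEF randomization cells (reference level dropped).

* **Negative binomial rate** (primary): per-patient composite counts,
  $\log \mathbb{E}[y_i] = \log t_i + \alpha + x_i^\top\gamma + \beta a_i$,
  variance $\mu + \kappa\mu^2$. The $\sum_i[\log\Gamma(y_i+1/\kappa) -
  \log\Gamma(1/\kappa)]$ term is evaluated as
  $\sum_j \#\{y_i > j\}\log(1/\kappa + j)$, which collapses the expensive
  special-function work to one log per distinct count level and makes a
  6001-patient, 16 000-iteration fit run in a few seconds.
* **Piecewise-exponential recurrent events**: proportional intensity with a
  piecewise-constant baseline on segments cut at observed event-time
  deciles (10 segments by default, exposed via `pwe_cutpoints`), optional
  gamma frailty marginalized in closed form. This is the parametric analog
  of an Andersen–Gill / LWYY fit; the robust-variance construction of LWYY
  has no direct Bayesian counterpart, so the package provides both this
  model and the negative binomial (which the source analysis itself reports
  as giving a near-identical rate ratio). Likelihood modes agree with an
  established Andersen–Gill fitter to < 0.02 on the log scale in tests.
* **Piecewise-exponential time-to-event**: same machinery with at most one
  event per patient; the parametric analog of a stratified Cox model.
  Baselines are proportional across strata (stratum fixed effects) by
  default rather than fully stratified — at trial scale the treatment-effect
  estimates agree closely and the parameter count stays small enough for
  the sampler to mix well.
* **Poisson rate**: death counts with a log follow-up offset (used for
  absolute mortality rates).
* **Logistic**: strata-adjusted log odds ratio for binary safety /
  functional-class outcomes; 2000 iterations by default (half the efficacy
  default), matching the analysis convention for safety endpoints.

Degenerate inputs are rejected with explicit messages: non-positive
follow-up, zero-event time-to-event outcomes, zero-variation binary
outcomes, missing flags. Fitting any model to an **empty cohort** returns
the prior (prior-predictive mode), which the tests exploit as a
prior-propagation check. Piecewise segments with no exposure are collapsed
with a warning.

## 4. Posterior computation

No probabilistic-programming backend is used; the package implements its
own samplers behind a pluggable contract (batched log-density in, draws
out; same backend + seed + config ⇒ bit-identical draws):

* **`laplace_imh`** (default): find the posterior mode
  (Nelder–Mead then BFGS), take the inverse negative Hessian, refine the
  proposal by a short importance-sampling pilot (weighted mean/covariance
  under a heavy-tailed Student-t centred at the mode — this captures
  skew-widened scales the curvature misses), then run independence
  Metropolis–Hastings with a multivariate-t proposal (df 10, covariance
  inflation 1.05) across all chains simultaneously. Mid-warmup the proposal
  moments are re-estimated once from the pooled history, which prevents the
  classic independence-sampler failure of sticking at states with a high
  target/proposal ratio. On the GLM-type posteriors here this yields
  acceptance rates of 0.5–0.8 and R-hat ≈ 1.00x at the default
  4 chains × 4000 iterations (50% burn-in).
* **`rwm`**: preconditioned adaptive random-walk Metropolis
  (Robbins–Monro scale adaptation to 30% acceptance, covariance re-estimated
  mid-warmup) as a fallback for posteriors where a mode-centred independence
  proposal is inadequate.

Diagnostics are rank-normalized split R-hat and bulk/tail ESS (via
`arviz`), computed for every fit; parameters with R-hat > 1.01 (or
undefined, as for degenerate constant chains) are flagged, fits warn, and
the CLI refuses to summarize flagged fits unless forced.

## 5. Reporting

Point estimates are posterior **medians**, intervals equal-tailed 95%
credible intervals computed on the log scale and exponentiated — both
choices are invariant/equivariant under the log transform, which the tests
assert exactly. Threshold probabilities use strict `<` at
1.0 / 0.9 / 0.85 / 0.8 (immaterial for continuous posteriors).
Standardized rates use empirical g-computation over the analyzed cohort:
each draw predicts every patient's event rate under both counterfactual
arms holding their stratum, averages over patients, and scales to 100
person-years; the rate difference is placebo − active (positive = fewer
events on treatment). Probability-threshold curves evaluate
$P(\text{ratio} < t)$ on a ratio grid and $P(\Delta > d)$ on an
absolute-difference grid. Printed-table parity uses half-up rounding
(probabilities to whole percent, log means to 3 decimals, SDs to 2).

## 6. Problem sizes used in the checks

The acceptance computation fits the full 6001-patient calibrated trial
twelve times at the default MCMC settings (a few minutes in total). With
the calibrated overdispersion, a single replicate's posterior median
rate ratio scatters with an SD of ≈ 0.06 on the ratio scale — the same
width as the published credible interval — so a 12-replicate mean is
reproducible to roughly ±0.05 (3 MC SEs), which is the agreement level the
corresponding test asserts against the printed 0.84. Pinning the mean
inside the ±0.005 two-decimal rounding window would require on the order of
10³ replicates. Interval-coverage checks use 250 trials of 500 patients;
parameter-recovery checks use 5 replicates of 1200 patients.

## 7. What the synthetic data do and do not show

Passing tests demonstrate that the estimators recover the parameters of the
generating process the package assumes (proportional intensities, shared
gamma frailty, exponential deaths, independent censoring, time-constant
safety risks) and that the prior arithmetic matches the published table
exactly. They do not validate those structural assumptions against the real
trial: covariate-dependent effects, non-proportional hazards, informative
dropout, longitudinal quality-of-life trajectories and adjudication effects
are all outside the generator (and out of scope). Patient-level posterior
results of the original analysis (e.g. its 0.83 [0.74–0.94] primary
estimate or its adjusted safety risk differences) require the
access-controlled trial data and are deliberately not acceptance targets;
the property battery (conjugate-oracle equivalence, frequentist
cross-checks, coverage, prior propagation) stands in for them.

## 8. Known limitations

* The MAP hyperprior and mixture-summarization rule of the source analysis
  are unknown; its printed MAP row cannot be reproduced exactly and is not
  claimed.
* The LWYY robust-variance estimator itself is not implemented — only its
  Bayesian analogs (negative binomial; PWE intensity with frailty).
* A single shared frailty shape cannot match all four printed count margins
  simultaneously (residual ≈ 2% on with-event counts).
* The independence sampler is tuned for unimodal, near-Gaussian posteriors;
  strongly multimodal posteriors would require the `rwm` backend or finer
  warmup, and ESS per iteration degrades for > ~30 parameters (one reason
  PWE baselines default to stratum-proportional rather than fully
  stratified).
* KCCQ-style longitudinal outcomes and composite kidney endpoints are out
  of scope.
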