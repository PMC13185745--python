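# bayesborrow

Bayesian dynamic borrowing for two-arm recurrent-event trials in heart
failure, built around the pre-specified Bayesian re-analysis of a large
HFmrEF/HFpEF outcome trial (~6000 patients, composite primary endpoint of
cardiovascular death and total heart-failure events).

The package is aimed at trial statisticians who want to

* turn **published summaries** of historical trials (point estimate +
  95% CI of a rate or hazard ratio) into downweighted normal priors and a
  **robust meta-analytic predictive (MAP) prior**,
* fit **Bayesian count, recurrent-event, survival and binary-outcome
  models** to patient-level two-arm data under vague or informative
  treatment priors, and
* report posterior medians, equal-tailed 95% credible intervals,
  **threshold probabilities** (P(RR < 1), P(RR < 0.9), ...) and
  **counterfactual standardized rates** per 100 person-years.

Because patient-level data from such trials are access-controlled, the
package ships a first-class synthetic-trial generator that reproduces the
statistical structure the analysis assumes (gamma-frailty recurrent events,
semi-competing death, stratified randomization, staggered-accrual
censoring), including a calibration routine that matches a generator
configuration to printed per-arm event margins.

## The model in brief

For a published ratio estimate $\hat\theta$ with a 95% CI $(L, U)$, the
downweighted prior on the log scale is

$$\beta \sim N\!\left(\ln\hat\theta,\; \big(k \cdot \tfrac{\ln U - \ln L}{2 z_{0.975}}\big)^2\right), \qquad k = 2,$$

i.e. the Wald standard error recovered from the CI, doubled. Several
studies are pooled by a normal-normal hierarchical model
$y_i \sim N(\theta_i, s_i^2)$, $\theta_i \sim N(\mu, \tau^2)$ with a
half-normal hyperprior on $\tau$; the MAP prior is the predictive
distribution of a new study's effect $\theta_{\text{new}}$, robustified as
$0.9 \cdot \text{MAP} + 0.1 \cdot N(0, 0.5)$.

The primary patient-level model is a negative binomial regression of
per-patient composite event counts with a log follow-up offset,
randomization-strata fixed effects and the treatment prior on the log rate
ratio $\beta$; piecewise-exponential recurrent-event (Andersen–Gill analog)
and time-to-event (Cox analog) likelihoods, Poisson death models and
strata-adjusted logistic models cover the remaining endpoints. Posterior
sampling is by an independence Metropolis–Hastings sampler with a
pilot-refined Student-t proposal (4 chains × 4000 iterations, 50% burn-in
by default) with rank-normalized split R-hat / ESS diagnostics via `arviz`.

## Worked example

```python
import numpy as np
from bayesborrow import (
    NegativeBinomialRateModel, TrialConfig, downweighted_prior, fit_map,
    generate_cohort, robustify, standardized_rates,
)
from bayesborrow.io import load_historical_estimates

# 1. priors from published summaries
ests = {e.study_id: e for e in load_historical_estimates()}
topcat = downweighted_prior(ests["TOPCAT"])
print(topcat)                          # GaussianPrior(mean=-0.174, sd=0.192)
print(round(100 * topcat.prob_below(1.0)))   # 82  (% prior probability RR < 1)

map_fit = fit_map([downweighted_prior(ests["TOPCAT-Americas"]),
                   downweighted_prior(ests["FIDELITY"])], seed=1)
robust = robustify(map_fit)            # 0.9 * MAP + 0.1 * N(0, 0.5)

# 2. a synthetic 6000-patient trial with a true rate ratio of 0.84
cohort = generate_cohort(TrialConfig(seed=7))

# 3. Bayesian negative binomial fit under the robust MAP prior
model = NegativeBinomialRateModel(treatment_prior=robust, seed=7).fit(cohort)
es = model.effect_summary()
print(round(es.point, 2), round(es.cri_low, 2), round(es.cri_high, 2))
print({t: round(p, 2) for t, p in es.threshold_probs.items()})

# 4. counterfactual standardized rates per 100 person-years
rp = standardized_rates(model.draws_, cohort)
print(round(rp.rate_placebo[0], 1), round(rp.rate_active[0], 1),
      round(rp.rate_difference[0], 1))
```

Running this prints (up to the seed):

```
GaussianPrior(mean=-0.1743533871447778, sd=0.1920839230743622)
82
0.82 0.76 0.9
{1.0: 1.0, 0.9: 0.98, 0.85: 0.76, 0.8: 0.25}
23.5 19.3 4.1
```

— the prior reproduces the published table row (log mean −0.174, doubled SD
0.19, 82% prior probability of benefit); the fitted rate ratio of 0.82
(95% CrI 0.76–0.90) recovers the generating effect of 0.84 with a 98%
posterior probability of a ≥10% rate reduction in this realization; and the
treatment saves about 4.1 composite events per 100 person-years in this
synthetic cohort (placebo 23.5, active 19.3).

The same pipeline is scriptable from the shell:

```bash
bayesborrow priors   --out runs/priors
bayesborrow simulate --out runs/sim --seed 7
bayesborrow fit      --cohort runs/sim/cohort.csv --out runs/fits \
                     --model nb --outcome composite --prior map_robust \
                     --priors-file runs/priors/priors.json --seed 7
bayesborrow report   --runs runs/fits --out runs/report --cohort runs/sim/cohort.csv
```

## Layout

| module | contents |
| --- | --- |
| `bayesborrow.priors` | published estimates, downweighted/MAP/robust priors |
| `bayesborrow.simulate` | synthetic-trial generator, margins, calibration |
| `bayesborrow.models` | sklearn-style Bayesian estimators for the five likelihoods |
| `bayesborrow.sampling` | MCMC backends, draws container, diagnostics |
| `bayesborrow.summaries` | effect summaries, standardized rates, threshold curves |
| `bayesborrow.io`, `bayesborrow.cli` | file formats and the `bayesborrow` command |

See `docs/methods.md` for the full model descriptions, parameter defaults,
numerical choices and known limitations.
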