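"""Inference engine: conjugate oracles, frequentist cross-checks, recovery,
prior propagation, and input validation."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from bayesborrow import (
    GaussianPrior,
    LogisticModel,
    McmcConfig,
    MixturePrior,
    ModelSpec,
    NegativeBinomialRateModel,
    PoissonRateModel,
    RecurrentEventPWEModel,
    TimeToEventPWEModel,
    TrialConfig,
    fit_nb_rate,
    generate_cohort,
)
from bayesborrow.simulate import cohort_to_frame

from conftest import two_arm_count_frame

FLAT = GaussianPrior(0.0, 10.0)


def _aggregate_margin_frame() -> pd.DataFrame:
    """Per-patient composite counts matching the printed per-arm totals,
    with equal unit person-time per patient."""
    y_p = np.zeros(2998, dtype=int)
    y_p[:1283] = 1
    y_a = np.zeros(3003, dtype=int)
    y_a[:1083] = 1
    return two_arm_count_frame(y_p, y_a)


def test_nb_on_printed_margins_recovers_crude_rate_ratio():
    frame = _aggregate_margin_frame()
    m = NegativeBinomialRateModel(treatment_prior=FLAT, strata_adjustment=False,
                                  seed=1).fit(frame)
    es = m.effect_summary()
    assert round(es.point, 2) == 0.84
    assert m.diagnostics_.ok


def test_nb_null_by_label_shuffle(small_cohort):
    rng = np.random.default_rng(5)
    shuffled = small_cohort.copy()
    shuffled["arm"] = rng.permutation(shuffled["arm"].to_numpy())
    m = NegativeBinomialRateModel(treatment_prior=FLAT, iterations=2000, seed=2).fit(shuffled)
    b = m.draws_.get("beta")
    assert abs(np.median(b)) < 3 * b.std()


def test_poisson_rate_matches_conjugate_gamma_oracle():
    """Flat prior on log rates <=> per-arm Gamma(y, T) posteriors."""
    y_p, y_a, t = 500, 420, 10.0
    counts_p = np.full(100, 5)
    counts_a = np.concatenate([np.full(60, 7), np.full(40, 0)])  # 420 total
    frame = two_arm_count_frame(counts_p, counts_a, t_placebo=t, t_active=t)
    assert frame.query("arm == 'active'")["n_hf_events"].sum() == y_a
    m = PoissonRateModel(outcome="composite", treatment_prior=FLAT,
                         strata_adjustment=False, nuisance_prior_scale=20.0,
                         seed=3).fit(frame)
    flat = m.draws_.stacked()
    beta = flat[:, m.draws_.parameter_names.index("beta")]
    rng = np.random.default_rng(12345)
    n_mc = 2_000_000
    oracle = np.log(rng.gamma(y_a, 1.0, n_mc) / rng.gamma(y_p, 1.0, n_mc))
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    assert np.exp(np.quantile(beta, qs)) == pytest.approx(
        np.exp(np.quantile(oracle, qs)), abs=0.01
    )


def test_logistic_matches_beta_binomial_oracle():
    n, y_p, y_a = 2000, 142, 292
    frame = two_arm_count_frame(np.zeros(n, int), np.zeros(n, int))
    frame["k_flag"] = np.concatenate([
        (np.arange(n) < y_p).astype(int), (np.arange(n) < y_a).astype(int)
    ])
    m = LogisticModel(outcome_flag="k_flag", treatment_prior=FLAT,
                      strata_adjustment=False, nuisance_prior_scale=20.0,
                      iterations=4000, seed=4).fit(frame)
    flat = m.draws_.stacked()
    names = m.draws_.parameter_names
    logit_p = flat[:, names.index("intercept")]
    logit_a = logit_p + flat[:, names.index("beta")]
    p_p = 1.0 / (1.0 + np.exp(-logit_p))
    p_a = 1.0 / (1.0 + np.exp(-logit_a))
    from scipy import stats

    qs = [0.025, 0.5, 0.975]
    # flat prior on the logit <=> Beta(y, n - y) on the probability
    assert np.quantile(p_p, qs) == pytest.approx(stats.beta.ppf(qs, y_p, n - y_p), abs=0.005)
    assert np.quantile(p_a, qs) == pytest.approx(stats.beta.ppf(qs, y_a, n - y_a), abs=0.005)
    # unadjusted risk difference close to the generating 7.5 percentage points
    assert 100 * np.median(p_a - p_p) == pytest.approx(7.5, abs=1.0)


def test_logistic_null_odds_ratio_centered_at_one():
    n = 1000
    frame = two_arm_count_frame(np.zeros(n, int), np.zeros(n, int))
    frame["flag"] = np.concatenate([(np.arange(n) < 100).astype(int)] * 2)
    m = LogisticModel(outcome_flag="flag", iterations=2000, seed=6).fit(frame)
    b = m.draws_.get("beta")
    assert abs(np.median(b)) < 3 * b.std() / math.sqrt(200)


def test_tte_pwe_mode_matches_cox_partial_likelihood():
    lifelines = pytest.importorskip("lifelines")
    cohort = generate_cohort(TrialConfig(n_per_arm=250, frailty_shape=5.0,
                                         cv_death_rate=0.08, noncv_death_rate=0.06, seed=7))
    frame = cohort_to_frame(cohort)
    m = TimeToEventPWEModel(outcome="all_death", treatment_prior=FLAT,
                            nuisance_prior_scale=20.0, strata_adjustment=False,
                            n_segments=20)
    beta_hat = m.posterior_mode(frame)["beta"]
    df = pd.DataFrame({
        "T": frame["followup_years"],
        "E": (frame["died_cv"].astype(bool) | frame["died_other"].astype(bool)).astype(int),
        "arm": (frame["arm"] == "active").astype(int),
    })
    cox = lifelines.CoxPHFitter().fit(df, "T", "E").params_["arm"]
    assert beta_hat == pytest.approx(cox, abs=0.02)


def _counting_process_frame(cohort) -> pd.DataFrame:
    rows = []
    for r in cohort:
        prev = 0.0
        for t in r.hf_event_times:
            rows.append((r.patient_id, prev, t, 1, int(r.arm == "active")))
            prev = t
        if r.followup_years > prev:
            rows.append((r.patient_id, prev, r.followup_years, 0, int(r.arm == "active")))
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event", "arm"])


def test_recurrent_pwe_mode_matches_andersen_gill_fitter():
    lifelines = pytest.importorskip("lifelines")
    cohort = generate_cohort(TrialConfig(n_per_arm=100, frailty_shape=5.0, seed=9))
    frame = cohort_to_frame(cohort)
    m = RecurrentEventPWEModel(treatment_prior=FLAT, nuisance_prior_scale=20.0,
                               strata_adjustment=False, n_segments=10)
    beta_hat = m.posterior_mode(frame)["beta"]
    ag = lifelines.CoxTimeVaryingFitter().fit(
        _counting_process_frame(cohort), id_col="id", start_col="start",
        stop_col="stop", event_col="event",
    ).params_["arm"]
    assert beta_hat == pytest.approx(ag, abs=0.02)


def test_recurrent_pwe_without_frailty_is_segmented_poisson():
    """The no-frailty likelihood must equal the Poisson likelihood on
    patient x segment expanded data."""
    cohort = generate_cohort(TrialConfig(n_per_arm=40, seed=13))
    frame = cohort_to_frame(cohort)
    m = RecurrentEventPWEModel(strata_adjustment=False, n_segments=4)
    data = m._prepare(frame)
    theta = np.array([[0.1, -1.0, -0.8, -1.2, -0.9], [0.0, -1.5, -1.5, -1.5, -1.5]])
    got = m._loglik(data, theta)
    lam = np.exp(theta[:, 1:])                       # (m, S)
    risk = np.exp(data["Xc"] @ theta[:, :1].T)       # (n, m)
    mu = (data["E"] @ lam.T) * risk
    manual = (
        (data["D"].sum(axis=0) @ theta[:, 1:].T)
        + data["n_i"] @ np.log(risk)
        - mu.sum(axis=0)
    )
    assert got == pytest.approx(manual, rel=1e-12)


def test_recurrent_pwe_recovers_true_rate_ratio():
    true_rr = 0.84
    medians, sds = [], []
    for seed in (101, 102, 103, 104, 105):
        cfg = TrialConfig(n_per_arm=600, frailty_shape=2.0,
                          true_log_rr=math.log(true_rr), seed=seed)
        frame = cohort_to_frame(generate_cohort(cfg))
        m = RecurrentEventPWEModel(frailty=True, treatment_prior=FLAT,
                                   iterations=2000, seed=seed).fit(frame)
        b = m.draws_.get("beta")
        medians.append(np.median(b))
        sds.append(b.std())
    pooled = float(np.mean(medians))
    mc_se = float(np.mean(sds)) / math.sqrt(len(medians))
    assert pooled == pytest.approx(math.log(true_rr), abs=3 * mc_se)


def test_tte_pwe_recovers_known_hazard_ratio():
    rng = np.random.default_rng(77)
    n, hr, base = 2500, 0.8, 0.30
    t_p = rng.exponential(1.0 / base, n)
    t_a = rng.exponential(1.0 / (base * hr), n)
    cens = 3.0
    frame = two_arm_count_frame(np.zeros(n, int), np.zeros(n, int))
    times = np.concatenate([t_p, t_a])
    frame["followup_years"] = np.minimum(times, cens)
    frame["died_cv"] = (times < cens).astype(int)
    m = TimeToEventPWEModel(outcome="cv_death", treatment_prior=FLAT,
                            iterations=2000, n_segments=8, seed=15).fit(frame)
    b = m.draws_.get("beta")
    assert np.median(b) == pytest.approx(math.log(hr), abs=3 * b.std())


# ---------------------------------------------------------------------------
# prior propagation (empty-data fits return the prior)
# ---------------------------------------------------------------------------

PRIOR = GaussianPrior(-0.15, 0.35)


@pytest.mark.parametrize(
    "make",
    [
        lambda: NegativeBinomialRateModel(treatment_prior=PRIOR, iterations=2000, seed=21),
        lambda: PoissonRateModel(treatment_prior=PRIOR, iterations=2000, seed=22),
        lambda: LogisticModel(treatment_prior=PRIOR, iterations=2000, seed=23),
        lambda: TimeToEventPWEModel(treatment_prior=PRIOR, iterations=2000, seed=24,
                                    pwe_cutpoints=[1.0]),
        lambda: RecurrentEventPWEModel(treatment_prior=PRIOR, iterations=2000, seed=25,
                                       pwe_cutpoints=[1.0]),
    ],
    ids=["nb", "poisson", "logistic", "tte_pwe", "recurrent_pwe"],
)
def test_empty_data_posterior_equals_prior(empty_cohort, make):
    m = make().fit(empty_cohort)
    b = m.draws_.get("beta")
    assert np.mean(b) == pytest.approx(PRIOR.mean, abs=0.04)
    assert np.std(b) == pytest.approx(PRIOR.sd, abs=0.04)
    for q, z in ((0.025, -1.959964), (0.975, 1.959964)):
        assert np.quantile(b, q) == pytest.approx(PRIOR.mean + z * PRIOR.sd, abs=0.1)


def test_empty_data_mixture_prior_propagates(empty_cohort):
    mix = MixturePrior(((0.9, GaussianPrior(-0.188, 0.2)), (0.1, GaussianPrior(0.0, 0.5))))
    m = NegativeBinomialRateModel(treatment_prior=mix, iterations=4000, seed=27).fit(empty_cohort)
    b = m.draws_.get("beta")
    for t in (1.0, 0.9, 0.85, 0.8):
        assert np.mean(b < math.log(t)) == pytest.approx(mix.prob_below(t), abs=0.03)


def test_informative_prior_shrinkage_is_between_vague_and_prior():
    cfg = TrialConfig(n_per_arm=400, true_log_rr=0.0, frailty_shape=3.0, seed=31)
    frame = cohort_to_frame(generate_cohort(cfg))
    prior = GaussianPrior(math.log(0.7), 0.12)
    vague = NegativeBinomialRateModel(treatment_prior=FLAT, iterations=2000, seed=32).fit(frame)
    inf = NegativeBinomialRateModel(treatment_prior=prior, iterations=2000, seed=32).fit(frame)
    b_vague = float(np.median(vague.draws_.get("beta")))
    b_inf = float(np.median(inf.draws_.get("beta")))
    lo, hi = sorted([b_vague, prior.mean])
    assert lo < b_inf < hi


# ---------------------------------------------------------------------------
# validation and wrappers
# ---------------------------------------------------------------------------

def test_zero_followup_rejected():
    frame = two_arm_count_frame(np.zeros(3, int), np.zeros(3, int))
    frame.loc[0, "followup_years"] = 0.0
    with pytest.raises(ValueError, match="followup"):
        NegativeBinomialRateModel(iterations=200, seed=1).fit(frame)


def test_zero_event_tte_rejected(small_cohort):
    frame = small_cohort.copy()
    frame["died_cv"] = 0
    with pytest.raises(ValueError, match="zero events"):
        TimeToEventPWEModel(outcome="cv_death", iterations=200, seed=1).fit(frame)


def test_constant_safety_outcome_rejected(small_cohort):
    frame = small_cohort.copy()
    frame["k_gt_5_5"] = 1
    with pytest.raises(ValueError, match="no variation"):
        LogisticModel(outcome_flag="k_gt_5_5", iterations=200, seed=1).fit(frame)
    with pytest.raises(ValueError, match="not present"):
        LogisticModel(outcome_flag="no_such_flag", iterations=200, seed=1).fit(frame)


def test_spec_wrappers_dispatch_and_validate(small_cohort):
    spec = ModelSpec(likelihood="neg_binomial_rate")
    draws = fit_nb_rate(small_cohort, spec, McmcConfig(iterations=500, seed=2))
    assert "beta" in draws.parameter_names
    assert draws.n_chains == 4
    with pytest.raises(ValueError):
        fit_nb_rate(small_cohort, ModelSpec(likelihood="logistic"))
    with pytest.raises(ValueError):
        ModelSpec(likelihood="weibull")
    with pytest.raises(ValueError):
        ModelSpec(likelihood="tte_pwe", pwe_cutpoints=[2.0, 1.0])
    with pytest.raises(ValueError):
        McmcConfig(chains=1)


def test_fit_diagnostics_clean_on_standard_problem(small_cohort):
    m = NegativeBinomialRateModel(iterations=2000, seed=41).fit(small_cohort)
    assert m.diagnostics_.ok
    assert set(m.parameter_names_) == set(m.draws_.parameter_names)
    assert "log_kappa" in m.parameter_names_


def test_sklearn_params_roundtrip():
    m = NegativeBinomialRateModel(iterations=500, seed=1)
    params = m.get_params()
    assert params["iterations"] == 500
    m2 = NegativeBinomialRateModel(**params)
    assert m2.get_params() == params
    m2.set_params(seed=9)
    assert m2.seed == 9
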