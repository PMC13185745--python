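"""Construction of informative priors from published trial summaries.

Historical trials report a ratio effect (rate ratio or hazard ratio) with a
95% confidence interval.  On the log scale such an interval is Wald-type, so
the printed bounds recover the standard error, which is then inflated
(doubled by default) to discount the historical information by half.  Several
downweighted studies can be pooled into a meta-analytic predictive (MAP)
prior -- the predictive distribution of a new study's effect under a
normal-normal hierarchical model -- and robustified by mixing in a vague
component that guards against prior-data conflict.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence, Union

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .sampling import PosteriorDraws, sample_posterior

__all__ = [
    "PublishedEstimate",
    "GaussianPrior",
    "MixturePrior",
    "MapModelConfig",
    "MapPriorFit",
    "downweighted_prior",
    "prior_prob_below",
    "fit_map",
    "robustify",
    "moment_match",
]

_EFFECT_MEASURES = ("rate_ratio", "hazard_ratio")


@dataclasses.dataclass(frozen=True)
class PublishedEstimate:
    """A printed ratio estimate with its confidence interval.

    ``point``, ``ci_lower`` and ``ci_upper`` are on the ratio scale
    (dimensionless, positive); ``ci_level`` is the nominal coverage of the
    interval (default 0.95).
    """

    study_id: str
    effect_measure: str
    point: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.effect_measure not in _EFFECT_MEASURES:
            raise ValueError(
                f"effect_measure must be one of {_EFFECT_MEASURES}, got {self.effect_measure!r}"
            )
        if not (0 < self.ci_lower <= self.point <= self.ci_upper):
            raise ValueError(
                f"{self.study_id}: require 0 < ci_lower <= point <= ci_upper, "
                f"got {self.ci_lower}, {self.point}, {self.ci_upper}"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"{self.study_id}: ci_level must be in (0, 1)")


@dataclasses.dataclass(frozen=True)
class GaussianPrior:
    """Normal prior on the log of a ratio effect; ``sd`` is a standard deviation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def prob_below(self, ratio_threshold: float = 1.0) -> float:
        """P(effect ratio < ratio_threshold)."""
        if ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        return float(stats.norm.cdf((math.log(ratio_threshold) - self.mean) / self.sd))

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return stats.norm.logpdf(np.asarray(x, dtype=float), self.mean, self.sd)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed interval on the ratio scale."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return math.exp(self.mean - z * self.sd), math.exp(self.mean + z * self.sd)

    def to_dict(self) -> dict:
        return {"type": "normal", "mean": self.mean, "sd": self.sd}


@dataclasses.dataclass(frozen=True)
class MixturePrior:
    """Weighted mixture of normal components on the log-ratio scale."""

    components: tuple[tuple[float, GaussianPrior], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(w), c) for w, c in self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) < 1:
            raise ValueError("mixture needs at least one component")
        weights = np.array([w for w, _ in comps])
        if np.any(weights < 0):
            raise ValueError("mixture weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture weights must sum to 1, got {weights.sum()!r}")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    def prob_below(self, ratio_threshold: float = 1.0) -> float:
        return float(sum(w * c.prob_below(ratio_threshold) for w, c in self.components))

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        parts = np.stack([np.log(w) + c.logpdf(x) if w > 0 else np.full(x.shape, -np.inf)
                          for w, c in self.components])
        return logsumexp(parts, axis=0)

    def mean(self) -> float:
        return float(sum(w * c.mean for w, c in self.components))

    def variance(self) -> float:
        m = self.mean()
        return float(sum(w * (c.sd ** 2 + (c.mean - m) ** 2) for w, c in self.components))

    def to_dict(self) -> dict:
        return {
            "type": "mixture",
            "components": [
                {"weight": w, "mean": c.mean, "sd": c.sd} for w, c in self.components
            ],
        }


Prior = Union[GaussianPrior, MixturePrior]


@dataclasses.dataclass
class MapModelConfig:
    """Configuration of the hierarchical MAP model and its robustification.

    tau_prior_scale
        Scale of the half-normal hyperprior on the between-study
        heterogeneity SD (log-ratio units).
    robust_weight
        Mixture weight of the vague component added by :func:`robustify`.
    robust_component
        The vague component itself (default N(0, 0.5), matching the vague
        analysis prior).
    mu_prior_sd
        SD of the (near-flat) normal prior on the hierarchical mean.
    """

    tau_prior_scale: float = 0.5
    robust_weight: float = 0.10
    robust_component: GaussianPrior = dataclasses.field(
        default_factory=lambda: GaussianPrior(0.0, 0.5)
    )
    mu_prior_sd: float = 10.0

    def __post_init__(self) -> None:
        if not self.tau_prior_scale > 0:
            raise ValueError("tau_prior_scale must be positive")
        if not 0.0 <= self.robust_weight <= 1.0:
            raise ValueError("robust_weight must be in [0, 1]")


def downweighted_prior(est: PublishedEstimate, inflation_factor: float = 2.0) -> GaussianPrior:
    """Turn a published ratio estimate into a downweighted normal prior.

    The log point estimate becomes the prior mean; the Wald standard error
    recovered from the confidence interval, multiplied by
    ``inflation_factor`` (2 = discount the historical information by half),
    becomes the prior SD.
    """
    if inflation_factor < 1.0:
        raise ValueError("inflation_factor must be >= 1")
    if est.ci_lower == est.ci_upper:
        raise ValueError(
            f"study {est.study_id!r}: degenerate confidence interval "
            f"({est.ci_lower}, {est.ci_upper}) carries no standard error"
        )
    z = float(stats.norm.ppf(0.5 + est.ci_level / 2.0))
    se = (math.log(est.ci_upper) - math.log(est.ci_lower)) / (2.0 * z)
    return GaussianPrior(mean=math.log(est.point), sd=float(inflation_factor * se))


def prior_prob_below(prior: Prior, ratio_threshold: float = 1.0) -> float:
    """Prior probability that the effect ratio is below ``ratio_threshold``."""
    return prior.prob_below(ratio_threshold)


def moment_match(mix: MixturePrior) -> GaussianPrior:
    """The normal with the mixture's exact first two moments (law of total variance)."""
    return GaussianPrior(mean=mix.mean(), sd=math.sqrt(mix.variance()))


@dataclasses.dataclass
class MapPriorFit:
    """Result of fitting the hierarchical MAP model.

    Attributes
    ----------
    predictive
        Moment-matched normal summary of the predictive distribution of a
        new study's log effect.
    predictive_draws
        Raw draws of the new-study effect theta_new = mu + tau * z.
    draws
        Posterior draws of (mu, log_tau) with diagnostics.
    """

    predictive: GaussianPrior
    predictive_draws: np.ndarray
    draws: PosteriorDraws
    config: MapModelConfig


def fit_map(
    components: Sequence[GaussianPrior],
    config: MapModelConfig | None = None,
    n_draws: int = 20000,
    seed: int | None = None,
    chains: int = 4,
    backend: str = "laplace_imh",
) -> MapPriorFit:
    """Normal-normal hierarchical meta-analysis and its predictive distribution.

    Each component summarizes one historical study's likelihood: mean = the
    study log effect, sd = its (downweighted) standard error.  Study effects
    theta_i ~ N(mu, tau^2) with observed means ~ N(theta_i, sd_i^2); mu gets a
    near-flat normal prior and tau a half-normal(0, tau_prior_scale)
    hyperprior.  The study effects are marginalized analytically, so only
    (mu, log tau) are sampled.  Raises :class:`ConvergenceError` if R-hat
    exceeds 1.01.
    """
    if len(components) < 1:
        raise ValueError("fit_map needs at least one study component")
    config = config or MapModelConfig()
    y = np.array([c.mean for c in components])
    s2 = np.array([c.sd ** 2 for c in components])
    scale = config.tau_prior_scale
    mu_sd = config.mu_prior_sd

    def _mu_conditional(tau2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Conjugate posterior of mu given tau: precision a, mean b/a."""
        v = s2[None, :] + tau2[:, None]
        a = 1.0 / mu_sd ** 2 + np.sum(1.0 / v, axis=1)
        b = np.sum(y[None, :] / v, axis=1)
        return a, b / a

    def log_post(x: np.ndarray) -> np.ndarray:
        # mu marginalized analytically; only log tau is sampled
        log_tau = np.clip(x[:, 0], -30.0, 30.0)
        tau2 = np.exp(2.0 * log_tau)
        v = s2[None, :] + tau2[:, None]
        a, m = _mu_conditional(tau2)
        ll = (
            -0.5 * np.sum(np.log(2.0 * np.pi * v) + y[None, :] ** 2 / v, axis=1)
            + 0.5 * a * m ** 2
            - 0.5 * np.log(a * mu_sd ** 2)
        )
        # half-normal on tau, sampled on the log scale (jacobian = log_tau)
        return ll - 0.5 * (tau2 / scale ** 2) + log_tau

    iterations = max(200, int(math.ceil(2.0 * n_draws / chains)))
    raw = sample_posterior(
        log_post, np.array([math.log(scale / 2.0)]), param_names=["log_tau"],
        chains=chains, iterations=iterations, warmup_fraction=0.5, seed=seed,
        backend=backend, check_convergence=True,
    )
    log_tau = raw.draws[:, :, 0]
    tau2 = np.exp(2.0 * log_tau)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    a, m = (arr.reshape(log_tau.shape) for arr in _mu_conditional(tau2.reshape(-1)))
    mu = m + rng.standard_normal(log_tau.shape) / np.sqrt(a)
    theta_new = (mu + np.exp(log_tau) * rng.standard_normal(log_tau.shape)).reshape(-1)
    from .sampling import _diagnostics_dict

    joint = np.stack([mu, log_tau], axis=2)
    draws = PosteriorDraws(["mu", "log_tau"], joint, _diagnostics_dict(joint, ["mu", "log_tau"]))
    # Moment-matched summary by deterministic quadrature over the 1-D tau
    # posterior: E[theta_new] = E[m(tau)],
    # Var[theta_new] = Var_tau(m) + E[1/a] + E[tau^2]  (law of total variance)
    center = float(np.median(log_tau))
    grid = np.linspace(center - 12.0, max(center + 4.0, math.log(scale) + 3.0), 1024)
    lw = log_post(grid[:, None])
    w = np.exp(lw - lw.max())
    w /= w.sum()
    tau2_g = np.exp(2.0 * grid)
    a_g, m_g = _mu_conditional(tau2_g)
    pred_mean = float(np.sum(w * m_g))
    pred_var = float(
        np.sum(w * (m_g - pred_mean) ** 2) + np.sum(w / a_g) + np.sum(w * tau2_g)
    )
    predictive = GaussianPrior(mean=pred_mean, sd=float(math.sqrt(pred_var)))
    return MapPriorFit(predictive=predictive, predictive_draws=theta_new,
                       draws=draws, config=config)


def robustify(map_prior: GaussianPrior | MapPriorFit, config: MapModelConfig | None = None) -> MixturePrior:
    """Mix a vague component into the MAP prior to protect against prior-data conflict."""
    config = config or MapModelConfig()
    comp = map_prior.predictive if isinstance(map_prior, MapPriorFit) else map_prior
    w = config.robust_weight
    components = []
    if w < 1.0:
        components.append((1.0 - w, comp))
    if w > 0.0:
        components.append((w, config.robust_component))
    return MixturePrior(tuple(components))
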