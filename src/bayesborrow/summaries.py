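"""Posterior reporting: medians, credible intervals, threshold probabilities,
counterfactual standardized rates, and probability-threshold curves.

Conventions: posterior point estimates are medians (invariant to the log
transform); intervals are equal-tailed 95% credible intervals computed on
the log scale and exponentiated, so scale equivariance holds exactly;
threshold probabilities use a strict "<".
"""

from __future__ import annotations

import dataclasses
import decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .sampling import PosteriorDraws

__all__ = [
    "EffectSummary",
    "RatePrediction",
    "summarize_effect",
    "standardized_rates",
    "threshold_curve",
    "absolute_threshold_curve",
    "round_half_up",
]

MIN_KEPT_DRAWS = 400
DEFAULT_THRESHOLDS = (1.0, 0.9, 0.85, 0.8)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (so 0.5 -> 1), matching printed-table style."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclasses.dataclass
class EffectSummary:
    """Posterior summary of a ratio effect."""

    effect_measure: str
    point: float
    cri_low: float
    cri_high: float
    threshold_probs: dict[float, float]

    def __post_init__(self) -> None:
        if not self.cri_low <= self.point <= self.cri_high:
            raise ValueError("credible interval must contain the posterior median")
        ts = sorted(self.threshold_probs, reverse=True)
        ps = [self.threshold_probs[t] for t in ts]
        if any(not 0.0 <= p <= 1.0 for p in ps):
            raise ValueError("threshold probabilities must be in [0, 1]")
        if any(p2 > p1 + 1e-12 for p1, p2 in zip(ps, ps[1:])):
            raise ValueError("threshold probabilities must be non-increasing as thresholds decrease")

    def as_row(self) -> dict:
        row = {
            "effect_measure": self.effect_measure,
            "estimate": self.point,
            "cri_low": self.cri_low,
            "cri_high": self.cri_high,
        }
        for t in sorted(self.threshold_probs, reverse=True):
            row[f"p_lt_{t:g}"] = self.threshold_probs[t]
        return row


@dataclasses.dataclass
class RatePrediction:
    """Arm-specific standardized event rates per 100 person-years.

    Each of ``rate_placebo``, ``rate_active`` and ``rate_difference`` is a
    ``(median, cri_low, cri_high)`` triple; the difference is placebo minus
    active, so positive values mean fewer events on treatment.
    """

    rate_placebo: tuple[float, float, float]
    rate_active: tuple[float, float, float]
    rate_difference: tuple[float, float, float]
    prob_fewer_events: float
    placebo_draws: np.ndarray = dataclasses.field(repr=False)
    active_draws: np.ndarray = dataclasses.field(repr=False)

    @property
    def difference_draws(self) -> np.ndarray:
        return self.placebo_draws - self.active_draws


def _check_draw_count(n: int) -> None:
    if n < MIN_KEPT_DRAWS:
        raise ValueError(
            f"only {n} kept draws; at least {MIN_KEPT_DRAWS} are required for "
            "stable tail probabilities"
        )


def summarize_effect(
    draws: PosteriorDraws,
    beta_name: str = "beta",
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    effect_measure: str = "rate_ratio",
    ci_level: float = 0.95,
) -> EffectSummary:
    """Posterior median, equal-tailed CrI, and threshold probabilities for a
    log-scale effect parameter.

    ``threshold_probs[t]`` is the fraction of draws with ``exp(beta) < t``.
    """
    b = draws.get(beta_name)
    _check_draw_count(b.size)
    a = (1.0 - ci_level) / 2.0
    lo, med, hi = np.quantile(b, [a, 0.5, 1.0 - a])
    probs = {float(t): float(np.mean(b < np.log(t))) for t in thresholds}
    return EffectSummary(
        effect_measure=effect_measure,
        point=float(np.exp(med)),
        cri_low=float(np.exp(lo)),
        cri_high=float(np.exp(hi)),
        threshold_probs=probs,
    )


def _rate_design_from_draws(draws: PosteriorDraws, cohort_frame: pd.DataFrame):
    """Reconstruct the strata design of a rate model from parameter names."""
    names = draws.parameter_names
    if "beta" not in names or "intercept" not in names:
        raise ValueError("draws do not look like a rate model (need beta and intercept)")
    strata_names = [n for n in names if n.startswith("strata[")]
    labels = cohort_frame["region"].astype(str) + "|" + cohort_frame["lvef_group"].astype(str)
    counts = labels.value_counts()
    known = {n[len("strata["):-1] for n in strata_names}
    extra = set(counts.index) - known
    if strata_names and len(extra) > 1:
        raise ValueError(
            f"cohort strata {sorted(extra)} not covered by the fitted model "
            "(covariate mismatch beyond the single reference level)"
        )
    weights = counts / counts.sum()
    flat = draws.stacked()
    beta = flat[:, names.index("beta")]
    intercept = flat[:, names.index("intercept")]
    coef = {n[len("strata["):-1]: flat[:, names.index(n)] for n in strata_names}
    return weights, beta, intercept, coef


def standardized_rates(
    draws: PosteriorDraws, cohort, per: float = 100.0
) -> RatePrediction:
    """Counterfactual g-computation of arm-specific standardized rates.

    For each posterior draw, every patient's expected event rate per
    person-year is predicted with their own stratum under arm = placebo and
    arm = active; the predictions are averaged over the analyzed cohort and
    scaled to ``per`` person-years.  Summaries are posterior medians with
    equal-tailed 95% CrIs.
    """
    from .models import _as_frame

    frame = _as_frame(cohort)
    weights, beta, intercept, coef = _rate_design_from_draws(draws, frame)
    _check_draw_count(beta.size)
    r_p = np.zeros_like(beta)
    r_a = np.zeros_like(beta)
    for label, w in weights.items():
        s = coef.get(label, 0.0)
        base = np.exp(intercept + s)
        r_p += w * base
        r_a += w * base * np.exp(beta)
    r_p = per * r_p
    r_a = per * r_a
    diff = r_p - r_a

    def q3(x: np.ndarray) -> tuple[float, float, float]:
        lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
        return float(med), float(lo), float(hi)

    return RatePrediction(
        rate_placebo=q3(r_p),
        rate_active=q3(r_a),
        rate_difference=q3(diff),
        prob_fewer_events=float(np.mean(diff > 0)),
        placebo_draws=r_p,
        active_draws=r_a,
    )


def threshold_curve(
    draws: PosteriorDraws,
    beta_name: str = "beta",
    ratio_grid: Sequence[float] = tuple(np.round(np.linspace(0.5, 1.1, 61), 3)),
) -> pd.DataFrame:
    """P(effect ratio < t) over a grid of ratio thresholds.

    Consistent with :func:`summarize_effect` at shared thresholds, and
    non-decreasing in the threshold by construction.
    """
    grid = np.asarray(sorted(ratio_grid), dtype=float)
    if np.any(grid <= 0):
        raise ValueError("ratio thresholds must be positive")
    b = draws.get(beta_name)
    probs = [float(np.mean(b < np.log(t))) for t in grid]
    return pd.DataFrame({"threshold": grid, "probability": probs})


def absolute_threshold_curve(
    prediction: RatePrediction,
    diff_grid: Sequence[float] = tuple(np.round(np.linspace(0.0, 8.0, 33), 3)),
) -> pd.DataFrame:
    """P(rate difference per 100 person-years > d): absolute-benefit curve."""
    grid = np.asarray(sorted(diff_grid), dtype=float)
    d = prediction.difference_draws
    probs = [float(np.mean(d > g)) for g in grid]
    return pd.DataFrame({"threshold": grid, "probability": probs})
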