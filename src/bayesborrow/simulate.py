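"""Synthetic two-arm trial cohorts with recurrent events and semi-competing death.

The generator emulates the statistical structure a recurrent-event heart
failure trial analysis assumes: 1:1 randomization stratified by region and
ejection-fraction group, overdispersed recurrent heart-failure events
(patient-level gamma frailty, so marginal counts are negative binomial),
cardiovascular and non-cardiovascular death as semi-competing risks,
administrative censoring from a staggered accrual window, and per-arm binary
safety outcomes.

All times are in years; rates are per person-year (multiply by 100 only at
reporting time).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TrialConfig",
    "PatientRecord",
    "ArmSummary",
    "CohortSummary",
    "SAFETY_FLAGS",
    "generate_cohort",
    "summarize_cohort",
    "calibrate_to_margins",
    "expected_margins",
    "cohort_to_frame",
    "frame_to_cohort",
]

SAFETY_FLAGS = ("k_gt_5_5", "k_lt_3_5", "sbp_lt_100", "creat_ge_2_5", "serious_ae")

REGIONS = ("R1", "R2", "R3", "R4")
LVEF_GROUPS = ("lt60", "ge60")

# per-arm event probabilities (placebo, active); chosen to be of the size a
# mineralocorticoid-antagonist trial reports: hyperkalaemia roughly doubles,
# hypokalaemia roughly halves, modest excesses of hypotension and creatinine
# rise, serious adverse events balanced.
DEFAULT_SAFETY_PROBS: dict[str, tuple[float, float]] = {
    "k_gt_5_5": (0.071, 0.146),
    "k_lt_3_5": (0.110, 0.061),
    "sbp_lt_100": (0.125, 0.181),
    "creat_ge_2_5": (0.027, 0.045),
    "serious_ae": (0.380, 0.380),
}


def _default_strata_probs() -> dict[tuple[str, str], float]:
    region_p = {"R1": 0.30, "R2": 0.25, "R3": 0.25, "R4": 0.20}
    return {(r, g): region_p[r] * 0.5 for r in REGIONS for g in LVEF_GROUPS}


@dataclasses.dataclass
class TrialConfig:
    """Generating parameters for a synthetic two-arm trial.

    Defaults describe a trial of roughly 6000 patients followed for a median
    of about 32 months, with a placebo composite event rate in the low-20s
    per 100 person-years and a true rate ratio of 0.84.

    Parameters
    ----------
    n_per_arm
        Patients per arm (overridden by ``n_placebo`` / ``n_active`` when
        set, for trials with slightly unequal arms).
    true_log_rr
        Treatment effect on the recurrent-event intensity (log rate ratio).
    baseline_rate
        Placebo heart-failure event intensity per person-year (frailty mean 1).
    frailty_shape
        Gamma frailty shape; frailty variance is 1/shape, so small values
        mean strong overdispersion and the Poisson limit is shape -> inf.
    cv_death_rate, noncv_death_rate
        Exponential death intensities per person-year (placebo scale).
    death_hr
        Hazard ratio for cardiovascular death under treatment.
    max_followup_years, admin_censor_spread
        Administrative censoring is uniform on
        [max_followup_years - admin_censor_spread, max_followup_years],
        mimicking staggered accrual with a common end date.
    shared_frailty_death
        If True (default) the patient frailty also scales the death
        intensities, inducing the positive association between event burden
        and death that a composite analysis implicitly assumes.
    """

    n_per_arm: int = 3000
    true_log_rr: float = math.log(0.84)
    baseline_rate: float = 0.20
    frailty_shape: float = 1.0
    cv_death_rate: float = 0.032
    noncv_death_rate: float = 0.028
    death_hr: float = 0.93
    max_followup_years: float = 3.4
    admin_censor_spread: float = 1.5
    strata_probs: dict = dataclasses.field(default_factory=_default_strata_probs)
    safety_probs: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_SAFETY_PROBS))
    shared_frailty_death: bool = True
    n_placebo: int | None = None
    n_active: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be positive")
        for name in ("baseline_rate", "cv_death_rate", "noncv_death_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_followup_years <= 0:
            raise ValueError("max_followup_years must be positive")
        if not 0 <= self.admin_censor_spread <= self.max_followup_years:
            raise ValueError("admin_censor_spread must lie in [0, max_followup_years]")
        total = sum(self.strata_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"strata_probs must sum to 1, got {total}")

    @property
    def arm_sizes(self) -> tuple[int, int]:
        """(placebo, active) arm sizes."""
        return (
            self.n_placebo if self.n_placebo is not None else self.n_per_arm,
            self.n_active if self.n_active is not None else self.n_per_arm,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata_probs"] = {f"{r}|{g}": p for (r, g), p in self.strata_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "strata_probs" in d and d["strata_probs"] is not None:
            d["strata_probs"] = {
                tuple(k.split("|")): v for k, v in d["strata_probs"].items()
            }
        if "safety_probs" in d and d["safety_probs"] is not None:
            d["safety_probs"] = {k: tuple(v) for k, v in d["safety_probs"].items()}
        return cls(**d)


@dataclasses.dataclass
class PatientRecord:
    """One randomized patient: stratum, follow-up, events, death, safety flags."""

    patient_id: str
    arm: str                        # "placebo" | "active"
    region: str
    lvef_group: str                 # "lt60" | "ge60"
    followup_years: float
    hf_event_times: tuple[float, ...]
    died_cv: bool
    died_other: bool
    safety: dict[str, bool]

    def __post_init__(self) -> None:
        if self.arm not in ("placebo", "active"):
            raise ValueError(f"bad arm {self.arm!r}")
        if self.followup_years < 0:
            raise ValueError("followup_years must be nonnegative")
        times = tuple(float(t) for t in self.hf_event_times)
        if any(t > self.followup_years + 1e-12 for t in times):
            raise ValueError("event times must not exceed follow-up")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("hf_event_times must be strictly increasing")
        if self.died_cv and self.died_other:
            raise ValueError("at most one cause of death")
        self.hf_event_times = times

    @property
    def n_hf_events(self) -> int:
        return len(self.hf_event_times)

    @property
    def n_composite_events(self) -> int:
        """Heart-failure events plus cardiovascular death."""
        return self.n_hf_events + int(self.died_cv)


@dataclasses.dataclass(frozen=True)
class ArmSummary:
    n_randomized: int
    n_with_event: int
    total_events: int
    person_years: float

    def __post_init__(self) -> None:
        if self.n_with_event > self.n_randomized:
            raise ValueError("n_with_event cannot exceed n_randomized")
        if self.total_events < self.n_with_event:
            raise ValueError("total_events cannot be below n_with_event")


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Per-arm composite event margins."""

    placebo: ArmSummary
    active: ArmSummary

    def events_per_patient_ratio(self) -> float:
        """Crude active/placebo ratio of composite events per randomized patient."""
        return (self.active.total_events / self.active.n_randomized) / (
            self.placebo.total_events / self.placebo.n_randomized
        )

    def to_dict(self) -> dict:
        return {arm: dataclasses.asdict(getattr(self, arm)) for arm in ("placebo", "active")}


def _expected_total_hf_events(config: TrialConfig) -> float:
    n_p, n_a = config.arm_sizes
    lam = config.baseline_rate * config.max_followup_years
    return lam * (n_p + n_a * math.exp(config.true_log_rr))


def generate_cohort(config: TrialConfig) -> list[PatientRecord]:
    """Simulate one cohort; deterministic given ``config.seed``.

    Each patient has an independent random substream keyed by (seed, arm,
    patient index), so enlarging an arm leaves previously generated patients
    unchanged.
    """
    if _expected_total_hf_events(config) > 1e7:
        raise ValueError(
            "configuration implies more than 1e7 expected events; "
            "rejecting runaway parameters"
        )
    strata = list(config.strata_probs.keys())
    strata_p = np.array([config.strata_probs[s] for s in strata])
    strata_p = strata_p / strata_p.sum()
    flag_names = list(config.safety_probs.keys())
    records: list[PatientRecord] = []
    n_p, n_a = config.arm_sizes
    for arm_code, arm, n_arm in ((0, "placebo", n_p), (1, "active", n_a)):
        hf_rate0 = config.baseline_rate * math.exp(arm_code * config.true_log_rr)
        cv0 = config.cv_death_rate * (config.death_hr if arm_code else 1.0)
        nc0 = config.noncv_death_rate
        for i in range(n_arm):
            rng = np.random.default_rng([config.seed, arm_code, i])
            region, lvef = strata[rng.choice(len(strata), p=strata_p)]
            u = rng.gamma(config.frailty_shape, 1.0 / config.frailty_shape)
            censor = config.max_followup_years - config.admin_censor_spread * rng.random()
            fr = u if config.shared_frailty_death else 1.0
            t_cv = rng.exponential(1.0 / (fr * cv0)) if cv0 > 0 else np.inf
            t_nc = rng.exponential(1.0 / (fr * nc0)) if nc0 > 0 else np.inf
            followup = min(censor, t_cv, t_nc)
            died_cv = t_cv < censor and t_cv <= t_nc
            died_other = (not died_cv) and t_nc < censor
            lam = u * hf_rate0 * followup
            n_events = rng.poisson(lam) if lam > 0 else 0
            times = tuple(np.sort(rng.random(n_events) * followup)) if n_events else ()
            safety = {
                f: bool(rng.random() < config.safety_probs[f][arm_code])
                for f in flag_names
            }
            records.append(
                PatientRecord(
                    patient_id=f"{arm[0].upper()}{i:05d}",
                    arm=arm,
                    region=region,
                    lvef_group=lvef,
                    followup_years=float(followup),
                    hf_event_times=times,
                    died_cv=bool(died_cv),
                    died_other=bool(died_other),
                    safety=safety,
                )
            )
    return records


def summarize_cohort(cohort: Sequence[PatientRecord] | pd.DataFrame) -> CohortSummary:
    """Exact per-arm composite-event margins (HF events + cardiovascular deaths)."""
    if isinstance(cohort, pd.DataFrame):
        cohort = frame_to_cohort(cohort)
    out = {}
    for arm in ("placebo", "active"):
        recs = [r for r in cohort if r.arm == arm]
        out[arm] = ArmSummary(
            n_randomized=len(recs),
            n_with_event=sum(1 for r in recs if r.n_composite_events > 0),
            total_events=sum(r.n_composite_events for r in recs),
            person_years=float(sum(r.followup_years for r in recs)),
        )
    return CohortSummary(placebo=out["placebo"], active=out["active"])


# ---------------------------------------------------------------------------
# Cohort <-> DataFrame
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient; event times kept as a semicolon-joined string."""
    rows = []
    for r in cohort:
        row = {
            "patient_id": r.patient_id,
            "arm": r.arm,
            "region": r.region,
            "lvef_group": r.lvef_group,
            "followup_years": r.followup_years,
            "hf_event_times": ";".join(repr(t) for t in r.hf_event_times),
            "n_hf_events": r.n_hf_events,
            "died_cv": int(r.died_cv),
            "died_other": int(r.died_other),
        }
        for f, v in r.safety.items():
            row[f] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    flag_cols = [c for c in frame.columns if c in SAFETY_FLAGS]
    records = []
    for row in frame.itertuples(index=False):
        times_str = getattr(row, "hf_event_times", "") or ""
        times = tuple(float(t) for t in str(times_str).split(";") if t not in ("", "nan"))
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                arm=row.arm,
                region=row.region,
                lvef_group=row.lvef_group,
                followup_years=float(row.followup_years),
                hf_event_times=times,
                died_cv=bool(row.died_cv),
                died_other=bool(row.died_other),
                safety={f: bool(getattr(row, f)) for f in flag_cols},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Expected margins (quadrature) and calibration
# ---------------------------------------------------------------------------

def _arm_expectations(
    config: TrialConfig, arm_code: int, n_u: int = 64, n_c: int = 32
) -> dict[str, float]:
    """Expected per-patient quantities for one arm by gamma/uniform quadrature."""
    lam0 = config.baseline_rate * math.exp(arm_code * config.true_log_rr)
    cv0 = config.cv_death_rate * (config.death_hr if arm_code else 1.0)
    nc0 = config.noncv_death_rate
    shape = config.frailty_shape
    # frailty nodes at gamma quantile midpoints, equal weights
    q = (np.arange(n_u) + 0.5) / n_u
    u = stats.gamma.ppf(q, shape, scale=1.0 / shape)
    # censoring nodes
    lo = config.max_followup_years - config.admin_censor_spread
    c = lo + (np.arange(n_c) + 0.5) / n_c * config.admin_censor_spread
    U, C = np.meshgrid(u, c, indexing="ij")
    fr = U if config.shared_frailty_death else np.ones_like(U)
    D = fr * (cv0 + nc0)
    lam = U * lam0
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.where(D > 0, (1.0 - np.exp(-D * C)) / np.where(D > 0, D, 1.0), C)
        p_cv = np.where(D > 0, (fr * cv0 / np.where(D > 0, D, 1.0)) * (1.0 - np.exp(-D * C)), 0.0)
        tot = lam + D
        p_zero = np.where(
            tot > 0,
            np.exp(-tot * C) + (fr * nc0 / np.where(tot > 0, tot, 1.0)) * (1.0 - np.exp(-tot * C)),
            1.0,
        )
    e_hf = lam * ef
    return {
        "events": float(np.mean(e_hf + p_cv)),
        "with_event": float(np.mean(1.0 - p_zero)),
        "person_years": float(np.mean(ef)),
    }


def expected_margins(config: TrialConfig) -> CohortSummary:
    """Expected cohort margins under the generating model (rounded to nearest count)."""
    n_p, n_a = config.arm_sizes
    out = {}
    for arm, code, n in (("placebo", 0, n_p), ("active", 1, n_a)):
        e = _arm_expectations(config, code)
        out[arm] = ArmSummary(
            n_randomized=n,
            n_with_event=int(round(n * e["with_event"])),
            total_events=int(round(n * e["events"])),
            person_years=n * e["person_years"],
        )
    return CohortSummary(placebo=out["placebo"], active=out["active"])


def median_followup(config: TrialConfig, tol: float = 1e-6) -> float:
    """Median of the follow-up distribution (both arms pooled)."""
    shape = config.frailty_shape
    lo = config.max_followup_years - config.admin_censor_spread
    n_p, n_a = config.arm_sizes
    w_a = n_a / (n_p + n_a)

    def surv(t: float) -> float:
        s = 0.0
        for code, w in ((0, 1.0 - w_a), (1, w_a)):
            D = config.cv_death_rate * (config.death_hr if code else 1.0) + config.noncv_death_rate
            if config.shared_frailty_death and D > 0:
                s_death = (shape / (shape + D * t)) ** shape
            else:
                s_death = math.exp(-D * t)
            if config.admin_censor_spread > 0:
                s_cens = min(1.0, max(0.0, (config.max_followup_years - t) / config.admin_censor_spread))
            else:
                s_cens = 1.0 if t < config.max_followup_years else 0.0
            s += w * s_death * s_cens
        return s

    if surv(lo) <= 0.5:
        a, b = 1e-9, lo if lo > 0 else config.max_followup_years
    else:
        a, b = lo, config.max_followup_years
    if surv(a) - 0.5 <= 0:
        return a
    return float(optimize.brentq(lambda t: surv(t) - 0.5, a, b, xtol=tol))


def calibrate_to_margins(
    target: CohortSummary,
    median_followup_years: float,
    base_config: TrialConfig | None = None,
) -> TrialConfig:
    """Solve for a generating configuration matching printed trial margins.

    Fits (baseline_rate, true_log_rr, frailty_shape, max_followup_years) by
    least squares so the expected per-arm total composite events, patients
    with an event, and the median follow-up match the target; death rates,
    censor spread and strata are taken from ``base_config`` (defaults).
    """
    for arm in ("placebo", "active"):
        s = getattr(target, arm)
        if s.total_events <= 0 or s.n_randomized <= 0:
            raise ValueError(f"{arm}: target counts must be positive")
        if s.total_events < s.n_with_event:
            raise ValueError(f"{arm}: total events below patients with events is infeasible")
    base = base_config or TrialConfig()

    t_ev = np.array([target.placebo.total_events, target.active.total_events], dtype=float)
    t_we = np.array([target.placebo.n_with_event, target.active.n_with_event], dtype=float)
    n = np.array([target.placebo.n_randomized, target.active.n_randomized], dtype=float)

    def build(x: np.ndarray) -> TrialConfig:
        log_lam, beta, log_shape, max_f = x
        return dataclasses.replace(
            base,
            baseline_rate=float(np.exp(log_lam)),
            true_log_rr=float(beta),
            frailty_shape=float(np.exp(log_shape)),
            max_followup_years=float(max_f),
            n_placebo=int(n[0]),
            n_active=int(n[1]),
        )

    t_py = np.array([target.placebo.person_years, target.active.person_years], dtype=float)
    use_py = bool(np.all(t_py > 0))

    # total events and follow-up are the margins the rate-ratio estimand
    # depends on, so they carry most of the weight; patients-with-event only
    # identifies the overdispersion
    def resid(x: np.ndarray) -> np.ndarray:
        cfg = build(x)
        e_p = _arm_expectations(cfg, 0)
        e_a = _arm_expectations(cfg, 1)
        ev = np.array([n[0] * e_p["events"], n[1] * e_a["events"]])
        we = np.array([n[0] * e_p["with_event"], n[1] * e_a["with_event"]])
        parts = [20.0 * (ev / t_ev - 1.0), we / t_we - 1.0]
        if use_py:
            py = np.array([n[0] * e_p["person_years"], n[1] * e_a["person_years"]])
            parts.append(20.0 * (py / t_py - 1.0))
        med = median_followup(cfg)
        parts.append(np.array([20.0 * (med / median_followup_years - 1.0)]))
        return np.concatenate(parts)

    rate0 = t_ev[0] / (n[0] * median_followup_years)
    beta0 = math.log((t_ev[1] / n[1]) / (t_ev[0] / n[0]))
    x0 = np.array([math.log(max(rate0, 1e-6)), beta0, 0.0, median_followup_years + base.admin_censor_spread / 2])
    lb = [-12.0, -3.0, -4.0, median_followup_years + 1e-3]
    ub = [3.0, 3.0, 6.0, median_followup_years + base.admin_censor_spread + 5.0]
    sol = optimize.least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    if not sol.success and np.max(np.abs(sol.fun)) > 0.02:
        raise RuntimeError(f"calibration failed to match margins: residuals {sol.fun}")
    return build(sol.x)
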