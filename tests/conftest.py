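import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bayesborrow import PublishedEstimate, TrialConfig, generate_cohort
from bayesborrow.simulate import cohort_to_frame

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_estimates() -> dict[str, PublishedEstimate]:
    """The published historical-trial summaries the informative priors come from."""
    return {
        "TOPCAT": PublishedEstimate("TOPCAT", "rate_ratio", 0.84, 0.70, 1.02),
        "TOPCAT-Americas": PublishedEstimate("TOPCAT-Americas", "rate_ratio", 0.79, 0.64, 0.97),
        "FIDELITY": PublishedEstimate("FIDELITY", "rate_ratio", 0.82, 0.72, 0.95),
    }


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 400-patient synthetic cohort with moderate overdispersion."""
    cfg = TrialConfig(n_per_arm=200, frailty_shape=2.0, seed=421)
    return cohort_to_frame(generate_cohort(cfg))


@pytest.fixture()
def empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "patient_id", "arm", "region", "lvef_group", "followup_years",
            "hf_event_times", "n_hf_events", "died_cv", "died_other",
        ]
    )


def two_arm_count_frame(
    y_placebo: np.ndarray,
    y_active: np.ndarray,
    t_placebo: float | np.ndarray = 1.0,
    t_active: float | np.ndarray = 1.0,
) -> pd.DataFrame:
    """Minimal cohort frame carrying per-patient composite counts."""
    n_p, n_a = len(y_placebo), len(y_active)
    t_p = np.broadcast_to(np.asarray(t_placebo, dtype=float), (n_p,))
    t_a = np.broadcast_to(np.asarray(t_active, dtype=float), (n_a,))
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n_p)] + [f"A{i}" for i in range(n_a)],
        "arm": ["placebo"] * n_p + ["active"] * n_a,
        "region": "R1",
        "lvef_group": "lt60",
        "followup_years": np.concatenate([t_p, t_a]),
        "hf_event_times": "",
        "n_hf_events": np.concatenate([y_placebo, y_active]).astype(int),
        "died_cv": 0,
        "died_other": 0,
    })
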