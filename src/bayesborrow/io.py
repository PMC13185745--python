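"""File formats: cohort CSV, study-estimate CSV, prior JSON, draws CSV.

Everything is plain text.  The cohort dialect is one row per patient with
recurrent event times serialized as a semicolon-delimited field; a sidecar
JSON carries the generating configuration when the cohort is synthetic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .priors import GaussianPrior, MixturePrior, Prior, PublishedEstimate
from .sampling import PosteriorDraws
from .simulate import PatientRecord, TrialConfig, cohort_to_frame, frame_to_cohort

__all__ = [
    "read_study_estimates",
    "load_historical_estimates",
    "write_cohort",
    "read_cohort",
    "prior_to_dict",
    "prior_from_dict",
    "write_priors",
    "read_priors",
    "write_draws",
    "read_draws",
    "provenance_record",
]


def read_study_estimates(path: str | Path) -> list[PublishedEstimate]:
    """Read published trial summaries (one record per study) from CSV."""
    frame = pd.read_csv(path)
    required = {"study_id", "effect_measure", "point", "ci_lower", "ci_upper"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"study file is missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PublishedEstimate(
                study_id=str(row.study_id),
                effect_measure=str(row.effect_measure),
                point=float(row.point),
                ci_lower=float(row.ci_lower),
                ci_upper=float(row.ci_upper),
                ci_level=float(getattr(row, "ci_level", 0.95)),
            )
        )
    return out


def load_historical_estimates() -> list[PublishedEstimate]:
    """The packaged historical-trial summaries (TOPCAT, TOPCAT-Americas, FIDELITY)."""
    with resources.as_file(
        resources.files("bayesborrow.data").joinpath("historical_trials.csv")
    ) as p:
        return read_study_estimates(p)


def write_cohort(cohort, path: str | Path, config: TrialConfig | None = None) -> Path:
    """Write a cohort CSV (and a ``.config.json`` sidecar when a config is given)."""
    path = Path(path)
    frame = cohort_to_frame(cohort) if not isinstance(cohort, pd.DataFrame) else cohort
    frame.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".config.json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n")
    return path


def read_cohort(path: str | Path, as_records: bool = False):
    frame = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                        dtype={"hf_event_times": str, "patient_id": str})
    frame["followup_years"] = frame["followup_years"].astype(float)
    return frame_to_cohort(frame) if as_records else frame


def prior_to_dict(prior: Prior) -> dict:
    return prior.to_dict()


def prior_from_dict(d: dict) -> Prior:
    if d["type"] == "normal":
        return GaussianPrior(mean=float(d["mean"]), sd=float(d["sd"]))
    if d["type"] == "mixture":
        return MixturePrior(tuple(
            (float(c["weight"]), GaussianPrior(float(c["mean"]), float(c["sd"])))
            for c in d["components"]
        ))
    raise ValueError(f"unknown prior type {d['type']!r}")


def write_priors(priors: dict[str, Prior], path: str | Path) -> Path:
    path = Path(path)
    payload = {name: prior_to_dict(p) for name, p in priors.items()}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def read_priors(path: str | Path) -> dict[str, Prior]:
    payload = json.loads(Path(path).read_text())
    return {name: prior_from_dict(d) for name, d in payload.items()}


def write_draws(draws: PosteriorDraws, path: str | Path) -> Path:
    """Columnar CSV: chain, iteration, then one column per parameter."""
    path = Path(path)
    draws.to_dataframe().to_csv(path, index=False)
    diag = {
        "parameter_names": draws.parameter_names,
        "diagnostics": draws.diagnostics,
    }
    path.with_suffix(".diagnostics.json").write_text(json.dumps(diag, indent=1) + "\n")
    return path


def read_draws(path: str | Path) -> PosteriorDraws:
    frame = pd.read_csv(path)
    names = [c for c in frame.columns if c not in ("chain", "iteration")]
    chains = int(frame["chain"].max()) + 1
    kept = int(frame["iteration"].max()) + 1
    arr = frame[names].to_numpy().reshape(chains, kept, len(names))
    diag_path = Path(path).with_suffix(".diagnostics.json")
    diagnostics = {}
    if diag_path.exists():
        diagnostics = json.loads(diag_path.read_text()).get("diagnostics", {})
    return PosteriorDraws(names, arr, diagnostics)


def provenance_record(command: str, config: dict, seed: int | None) -> dict:
    """Machine-readable record of a pipeline step: config hash, seed, version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "command": command,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "config": config,
    }
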