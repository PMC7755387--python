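"""Tidy-CSV readers/writers and YAML configuration.

The single interchange format is a long table with one row per
subject x environment x trial; schedule columns, behaviour columns and a
sparse ``rating`` column ride together so every pipeline stage is
agnostic to whether the data were simulated or imported.  Output files
carry a ``#``-prefixed metadata header (version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .choice import ChoiceFit, SessionData
from .cohort import Cohort
from .happiness import HappinessFit
from .task import TrialSchedule

SESSION_COLUMNS = [
    "subject", "environment", "trial", "best_car", "winner", "reward_A",
    "reward_B", "side_of_A", "is_rating_trial", "choice", "outcome",
    "obtained_points", "rating",
]
SCHEDULE_COLUMNS = SESSION_COLUMNS[:9]


def session_to_frame(session: SessionData) -> pd.DataFrame:
    frame = session.schedule.to_frame()
    frame.insert(0, "subject", session.subject)
    frame["choice"] = session.choices
    frame["outcome"] = session.outcomes
    frame["obtained_points"] = session.obtained_points
    rating = np.full(len(frame), np.nan)
    for t, r in session.ratings.items():
        rating[t - 1] = r
    frame["rating"] = rating
    return frame[SESSION_COLUMNS]


def frame_to_session(frame: pd.DataFrame) -> SessionData:
    _validate_columns(frame, SESSION_COLUMNS[:12])
    frame = frame.sort_values("trial").reset_index(drop=True)
    schedule = TrialSchedule.from_frame(frame)
    ratings = {}
    if "rating" in frame.columns:
        rated = frame.dropna(subset=["rating"])
        ratings = {int(r.trial): float(r.rating) for r in rated.itertuples()}
    return SessionData(
        schedule=schedule,
        choices=frame["choice"].to_numpy(dtype="U1"),
        outcomes=frame["outcome"].to_numpy(dtype=int),
        obtained_points=frame["obtained_points"].to_numpy(dtype=int),
        ratings=ratings,
        subject=str(frame["subject"].iloc[0]),
    )


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    parts = []
    for rec in cohort.subjects:
        for env in rec.task_order:
            part = session_to_frame(rec.sessions[env])
            part["symptom"] = rec.symptom
            parts.append(part)
    return pd.concat(parts, ignore_index=True)


def frame_to_sessions(frame: pd.DataFrame) -> dict[tuple[str, str], SessionData]:
    """Split a long cohort table into per-(subject, environment) sessions."""
    out = {}
    for (subject, env), part in frame.groupby(["subject", "environment"],
                                              sort=True):
        out[(str(subject), str(env))] = frame_to_session(part)
    return out


def choice_fits_to_frame(fits: list[ChoiceFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({
            "subject": f.subject, "environment": f.environment,
            "model": f.model_id, "alpha": f.params.alpha,
            "beta": f.params.beta, "phi": f.params.phi, "eta": f.params.eta,
            "log_lik": f.log_lik, "n_trials": f.n_trials,
            "pseudo_r2": f.pseudo_r2, "bic": f.bic, "converged": f.converged,
        })
    return pd.DataFrame(rows)


def happiness_fits_to_frame(fits: list[HappinessFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {"subject": f.subject, "environment": f.environment,
               "model": f.model_id, "w0": f.w0, "gamma": f.gamma,
               "rp": f.rp, "r2": f.r2, "var_explained": f.var_explained,
               "bic": f.bic, "n_ratings": f.n_ratings,
               "zscored": f.zscored, "flagged": f.flagged}
        row.update(f.weights)
        rows.append(row)
    return pd.DataFrame(rows)


def _validate_columns(frame: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed table: missing columns {missing}")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: str | Path, seed: int | None = None,
                config: dict | None = None) -> None:
    """Write a CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# banditmood version={__version__}"]
    if seed is not None:
        header.append(f"# seed={seed}")
    if config is not None:
        header.append(f"# config_hash={config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_session_table(path: str | Path) -> dict[tuple[str, str], SessionData]:
    frame = read_table(path)
    _validate_columns(frame, SESSION_COLUMNS[:12])
    return frame_to_sessions(frame)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return config
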