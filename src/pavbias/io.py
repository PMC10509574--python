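"""File-format contracts and run configuration.

Trial-level data travel as UTF-8 comma-separated text with one row per
trial and the column schema of :class:`~pavbias.task.TrialRecord`
(condition labels G2W/G2AP/NG2W/NG2AP, outcome in {-1, 0, 1}, response in
{left, right, none}, trial_index 0-based within session). Ground-truth
parameters ride in a sidecar CSV, fits in JSON. Every output file starts
with a comment header carrying the config hash and seed that produced it.

:class:`RunConfig` validates a YAML configuration file against a strict
schema (unknown keys rejected).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from pavbias.conditions import CONDITION_INDEX
from pavbias.fitting import FitOptions, GroupFit
from pavbias.task import SessionData, TrialRecord

__all__ = [
    "RunConfig", "load_config", "config_hash", "write_cohort_csv",
    "read_cohort_csv", "write_truth_csv", "read_truth_csv",
    "write_fit_json", "read_fit_json", "write_table",
]

TRIAL_COLUMNS = ["subject_id", "session", "block", "trial_index",
                 "condition", "target_side", "response", "action",
                 "correct", "outcome"]

_REQUIRED_READ = ["subject_id", "session", "block", "trial_index",
                  "condition", "target_side", "response", "outcome"]


class RunConfig(BaseModel):
    """Validated pipeline settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=100, ge=1)
    model: str = "RW(rew/pun)+noise+bias+pav(const)"
    n_sessions: int = Field(default=2, ge=1, le=2)
    n_blocks: int = Field(default=3, ge=1)
    per_cue_per_block: int = Field(default=10, ge=1)
    p_better: float = Field(default=0.8, ge=0.0, le=1.0)
    p_better_incorrect: float | None = Field(default=None, ge=0.0, le=1.0)
    side_error_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    between_session_correlation: float = Field(default=1.0, ge=0.0, le=1.0)
    seed: int = Field(default=0, ge=0)
    prior: dict[str, tuple[float, float]] | None = None
    localization_threshold: float = Field(default=0.45, ge=0.0, le=1.0)
    n_restarts: int = Field(default=5, ge=1)
    em_tol: float = Field(default=1e-3, gt=0.0)
    max_em_iter: int = Field(default=100, ge=1)
    n_mc_samples: int = Field(default=10_000, ge=100)
    penalty_obs: str = Field(default="choices", pattern="^(choices|subjects)$")

    def fit_options(self) -> FitOptions:
        return FitOptions(n_restarts=self.n_restarts, em_tol=self.em_tol,
                          max_em_iter=self.max_em_iter,
                          n_mc_samples=self.n_mc_samples,
                          penalty_obs=self.penalty_obs)


def load_config(path=None, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    data = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig | None, seed: int | None) -> str:
    h = config_hash(cfg) if cfg is not None else "none"
    return f"# pavbias config_hash={h} seed={seed}\n"


def write_table(df: pd.DataFrame, path, cfg: RunConfig | None = None,
                seed: int | None = None, index: bool = False) -> None:
    """CSV with the provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(cfg, seed))
        df.to_csv(fh, index=index)


def _sessions_from(cohort):
    for item in cohort:
        if isinstance(item, SessionData):
            yield item
        else:  # CohortSubject
            for sess in sorted(item.sessions):
                yield item.sessions[sess]


def write_cohort_csv(cohort, path, cfg: RunConfig | None = None,
                     seed: int | None = None) -> None:
    """One row per trial, all subject-sessions concatenated."""
    rows = []
    for session in _sessions_from(cohort):
        for t in session.trials:
            rows.append({
                "subject_id": t.subject_id, "session": t.session,
                "block": t.block, "trial_index": t.trial_index,
                "condition": t.condition, "target_side": t.target_side,
                "response": t.response, "action": t.action,
                "correct": t.correct, "outcome": t.outcome})
    write_table(pd.DataFrame(rows, columns=TRIAL_COLUMNS), path, cfg, seed)


def read_cohort_csv(path) -> list:
    """Parse a trial-level CSV back into per-subject-session records.

    Malformed rows (unknown condition labels, out-of-range outcomes,
    missing columns) are rejected with row-level diagnostics.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_READ if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    problems = []
    for i, row in df.iterrows():
        if row["condition"] not in CONDITION_INDEX:
            problems.append(f"row {i}: unknown condition "
                            f"{row['condition']!r}")
        if row["response"] not in ("left", "right", "none"):
            problems.append(f"row {i}: bad response {row['response']!r}")
        if int(row["outcome"]) not in (-1, 0, 1):
            problems.append(f"row {i}: outcome {row['outcome']!r} not in "
                            "{-1, 0, 1}")
        if len(problems) >= 20:
            problems.append("... (further problems suppressed)")
            break
    if problems:
        raise ValueError(f"{path}: malformed trial data:\n"
                         + "\n".join(problems))
    sessions = []
    for (sid, sess), grp in df.groupby(["subject_id", "session"], sort=True):
        grp = grp.sort_values("trial_index")
        trials = [TrialRecord(
            subject_id=str(sid), session=int(sess), block=int(r.block),
            trial_index=int(r.trial_index), condition=str(r.condition),
            target_side=str(r.target_side), response=str(r.response),
            outcome=int(r.outcome)) for r in grp.itertuples()]
        sessions.append(SessionData(subject_id=str(sid), session=int(sess),
                                    trials=trials))
    return sessions


def write_truth_csv(cohort, path, cfg: RunConfig | None = None,
                    seed: int | None = None) -> None:
    """Ground-truth generating parameters, one row per subject-session."""
    rows = []
    for subj in cohort:
        for sess in sorted(subj.true_params):
            row = {"subject_id": subj.subject_id, "session": sess}
            row.update(subj.true_params[sess].as_dict())
            rows.append(row)
    write_table(pd.DataFrame(rows), path, cfg, seed)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_fit_json(fit: GroupFit, path, cfg: RunConfig | None = None,
                   seed: int | None = None) -> None:
    """Serialize a group fit: hyperparameters, per-subject estimates, iBIC."""
    payload = {
        "model": fit.model_spec.name,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "seed": seed,
        "param_names": list(fit.model_spec.param_names),
        "prior_mean": fit.prior.mean.tolist(),
        "prior_var": fit.prior.var.tolist(),
        "n_em_iterations": fit.n_em_iterations,
        "converged": bool(fit.converged),
        "n_obs": fit.n_obs,
        "ibic": fit.ibic,
        "subjects": [
            {"subject_id": sid,
             "mode_unconstrained": post.mode.tolist(),
             "laplace_var": post.laplace_var.tolist(),
             "log_posterior_at_mode": post.log_posterior_at_mode,
             "converged": bool(post.converged),
             "estimates": est}
            for sid, post, est in zip(
                fit.subject_ids, fit.posteriors,
                fit.estimates.to_dict(orient="records"))
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
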