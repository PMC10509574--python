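"""Synthetic orthogonalized Go-NoGo task: schedules, outcomes, agents, cohorts.

The default session mirrors the study paradigm: 4 cue conditions x 30 trials
arranged in 3 blocks of 40, each cue appearing 10 times per block in random
order, with the target circle placed uniformly left/right. Feedback is
probabilistic: a correct Go/NoGo decision yields the better outcome (win
conditions: +1 vs 0; punishment conditions: 0 vs -1) with probability 0.8;
an incorrect decision yields it with the mirrored probability 0.2 (the
incorrect-side contingency is configurable since only the correct-side rule
is pinned down by the paradigm description).

Agents are simulated from any :class:`~pavbias.models.ModelSpec` with known
parameters, and two-session cohorts are generated with a controllable
between-session correlation of the per-subject true parameters, providing
ground truth for parameter-recovery and reliability experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from pavbias.conditions import CONDITIONS, CONDITION_INDEX, Condition, get_condition
from pavbias.models import (
    LearnerState,
    ModelSpec,
    ParameterSet,
    action_weights,
    choice_probability,
    learn_from_trial,
)

__all__ = [
    "Condition", "CONDITIONS", "TrialRecord", "SessionData", "CohortConfig",
    "CohortSubject", "generate_schedule", "realize_outcome", "simulate_agent",
    "generate_cohort", "default_group_prior_spec",
]

DEFAULT_N_BLOCKS = 3
DEFAULT_PER_CUE_PER_BLOCK = 10
DEFAULT_P_BETTER = 0.8


@dataclass
class TrialRecord:
    """One trial of one subject-session.

    `response` is the raw key press (left/right/none); `action` collapses it
    to the instrumental Go/NoGo dichotomy (any press counts as Go, even on
    the wrong side -- side errors matter only for the localization-error
    exclusion). `outcome` is the delivered reinforcement in {-1, 0, +1}.
    """

    subject_id: str
    session: int
    block: int
    trial_index: int
    condition: str
    target_side: str            # "left" | "right"
    response: str | None = None  # "left" | "right" | "none" | None (skeleton)
    outcome: int | None = None

    @property
    def action(self) -> str | None:
        if self.response is None:
            return None
        return "nogo" if self.response == "none" else "go"

    @property
    def correct(self) -> bool | None:
        if self.response is None:
            return None
        return self.action == get_condition(self.condition).correct_action


@dataclass
class SessionData:
    subject_id: str
    session: int
    trials: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class CohortConfig:
    """Generator settings for a synthetic one- or two-session cohort.

    `prior` maps each active parameter of `model_spec` to its group
    (mean, sd) in unconstrained space; per-subject session-2 parameters are
    drawn so the population correlation with session 1 equals
    `between_session_correlation` (a bivariate-Gaussian construction per
    parameter).
    """

    n_subjects: int
    model_spec: ModelSpec
    prior: Mapping[str, tuple]
    between_session_correlation: float = 1.0
    n_sessions: int = 2
    seed: int = 0
    n_blocks: int = DEFAULT_N_BLOCKS
    per_cue_per_block: int = DEFAULT_PER_CUE_PER_BLOCK
    p_better: float = DEFAULT_P_BETTER
    p_better_incorrect: float | None = None  # default: 1 - p_better
    side_error_rate: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.between_session_correlation <= 1.0:
            raise ValueError("between_session_correlation must lie in [0, 1]")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        missing = set(self.model_spec.param_names) - set(self.prior)
        if missing:
            raise ValueError(f"prior missing parameters: {sorted(missing)}")
        for name, (_, sd) in self.prior.items():
            if sd <= 0:
                raise ValueError(f"prior sd for {name} must be positive")


@dataclass
class CohortSubject:
    """Ground truth and simulated sessions for one synthetic subject."""

    subject_id: str
    true_params: dict          # session -> ParameterSet
    sessions: dict             # session -> SessionData


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_schedule(n_blocks: int = DEFAULT_N_BLOCKS,
                      per_cue_per_block: int = DEFAULT_PER_CUE_PER_BLOCK,
                      seed=0, subject_id: str = "sim",
                      session: int = 1) -> SessionData:
    """Trial-order skeleton: conditions shuffled within block, sides uniform.

    Every condition occurs exactly `per_cue_per_block` times in each block;
    responses and outcomes are left unset. `seed` may be an int or a
    numpy Generator.
    """
    if n_blocks < 1 or per_cue_per_block < 1:
        raise ValueError(
            "n_blocks and per_cue_per_block must be positive integers "
            f"(got {n_blocks}, {per_cue_per_block})")
    rng = _as_rng(seed)
    trials = []
    t = 0
    for block in range(1, n_blocks + 1):
        names = [c.name for c in CONDITIONS for _ in range(per_cue_per_block)]
        order = rng.permutation(len(names))
        for k in order:
            side = "left" if rng.random() < 0.5 else "right"
            trials.append(TrialRecord(
                subject_id=subject_id, session=session, block=block,
                trial_index=t, condition=names[k], target_side=side))
            t += 1
    return SessionData(subject_id=subject_id, session=session, trials=trials,
                       metadata={"n_blocks": n_blocks,
                                 "per_cue_per_block": per_cue_per_block})


def realize_outcome(condition, action: str, p_better: float, rng,
                    p_better_incorrect: float | None = None) -> int:
    """Sample the delivered outcome for one decision.

    A correct decision yields the condition's better outcome (win: +1,
    punishment: 0) with probability `p_better`; an incorrect decision with
    probability `p_better_incorrect` (defaults to the mirrored
    1 - p_better).
    """
    if not 0.0 <= p_better <= 1.0:
        raise ValueError(f"p_better must lie in [0, 1], got {p_better}")
    cond = get_condition(condition)
    if p_better_incorrect is None:
        p_better_incorrect = 1.0 - p_better
    correct = action == cond.correct_action
    p = p_better if correct else p_better_incorrect
    rng = _as_rng(rng)
    better = rng.random() < p
    return cond.better_outcome if better else cond.worse_outcome


def simulate_agent(model_spec: ModelSpec, params: ParameterSet,
                   schedule: SessionData, rng,
                   p_better: float = DEFAULT_P_BETTER,
                   p_better_incorrect: float | None = None,
                   side_error_rate: float = 0.0) -> SessionData:
    """Simulate a learner through a schedule, filling responses and outcomes.

    On each trial the agent's choice probability comes from the current
    action weights; a sampled Go is realized as a press on the target side
    (or, with `side_error_rate`, the wrong side -- an attention slip that
    does not alter the instrumental contingency). Outcomes feed the Q/V
    updates.
    """
    if params.spec != model_spec:
        raise ValueError(
            f"parameters were built for {params.spec.name!r}, "
            f"not {model_spec.name!r}")
    rng = _as_rng(rng)
    state = LearnerState()
    out = SessionData(subject_id=schedule.subject_id,
                      session=schedule.session,
                      metadata=dict(schedule.metadata))
    out.metadata.update({
        "model": model_spec.name,
        "true_params": params.as_dict(),
        "p_better": p_better,
    })
    for tr in schedule.trials:
        s = CONDITION_INDEX[get_condition(tr.condition).name]
        w_go, w_nogo = action_weights(s, state, params)
        p_go, _ = choice_probability(w_go, w_nogo, params.xi)
        go = rng.random() < p_go
        if go:
            wrong = rng.random() < side_error_rate
            if wrong:
                response = "left" if tr.target_side == "right" else "right"
            else:
                response = tr.target_side
        else:
            response = "none"
        action = "go" if go else "nogo"
        outcome = realize_outcome(tr.condition, action, p_better, rng,
                                  p_better_incorrect)
        out.trials.append(TrialRecord(
            subject_id=tr.subject_id, session=tr.session, block=tr.block,
            trial_index=tr.trial_index, condition=tr.condition,
            target_side=tr.target_side, response=response, outcome=outcome))
        learn_from_trial(state, s, action, outcome, params)
    return out


def default_group_prior_spec(spec: ModelSpec) -> dict:
    """Literature-typical generating prior, unconstrained (mean, sd) per name.

    Centres correspond to alpha ~ 0.2, rho ~ 4, xi ~ 0.1, b ~ 0.4,
    pi ~ 0.8 on the constrained scale, with moderate individual differences.
    """
    base = {
        "alpha": (-1.386, 0.7), "alpha_rew": (-1.386, 0.7),
        "alpha_pun": (-1.386, 0.7),
        "rho": (1.386, 0.5), "rho_rew": (1.386, 0.5), "rho_pun": (1.386, 0.5),
        "xi": (-2.197, 0.7),
        "b": (0.4, 0.5),
        "pi": (-0.223, 0.7),
    }
    return {name: base[name] for name in spec.param_names}


def _draw_subject_params(cfg: CohortConfig, rng: np.random.Generator):
    """Per-parameter bivariate-Gaussian draw across the two sessions."""
    names = cfg.model_spec.param_names
    rho_s = cfg.between_session_correlation
    x1 = np.empty(len(names))
    x2 = np.empty(len(names))
    for i, name in enumerate(names):
        m, sd = cfg.prior[name]
        z1, z2 = rng.standard_normal(2)
        x1[i] = m + sd * z1
        x2[i] = m + sd * (rho_s * z1 + np.sqrt(1.0 - rho_s ** 2) * z2)
    return x1, x2


def generate_cohort(cfg: CohortConfig) -> list:
    """Simulate a cohort of subjects with known ground-truth parameters.

    Returns a list of :class:`CohortSubject`. Child RNG streams are spawned
    per subject and session from the root seed, so per-subject data are
    reproducible regardless of iteration order.
    """
    from pavbias.models import to_constrained  # local to avoid cycle noise

    root = np.random.SeedSequence(cfg.seed)
    param_seq, *session_seqs = root.spawn(1 + cfg.n_sessions)
    param_rng = np.random.default_rng(param_seq)
    session_children = [seq.spawn(cfg.n_subjects) for seq in session_seqs]
    subjects = []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:04d}"
        x1, x2 = _draw_subject_params(cfg, param_rng)
        xs = {1: x1, 2: x2}
        true_params = {}
        sessions = {}
        for sess in range(1, cfg.n_sessions + 1):
            params = to_constrained(xs[sess], cfg.model_spec)
            child = np.random.default_rng(session_children[sess - 1][i])
            schedule = generate_schedule(
                cfg.n_blocks, cfg.per_cue_per_block, child,
                subject_id=sid, session=sess)
            data = simulate_agent(
                cfg.model_spec, params, schedule, child,
                p_better=cfg.p_better,
                p_better_incorrect=cfg.p_better_incorrect,
                side_error_rate=cfg.side_error_rate)
            data.metadata["seed"] = cfg.seed
            true_params[sess] = params
            sessions[sess] = data
        subjects.append(CohortSubject(sid, true_params, sessions))
    return subjects
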