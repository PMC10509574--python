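"""Rescorla-Wagner model family for the orthogonalized Go-NoGo task.

Each model variant assigns every cue s a pair of action values Q(go, s),
Q(nogo, s) learned by the delta rule

    Q_t = Q_{t-1} + alpha * (rho * r_t - Q_{t-1}),

where r in {-1, 0, +1} codes punishment / nothing / reward and rho scales the
subjective impact of the outcome. Action weights add a constant Go bias b and
a Pavlovian term driven by the cue's state value V(s), learned by the same
delta rule regardless of the action taken:

    W(go, s)   = Q(go, s) + b + pi * V(s)          (scaled variant)
    W(go, s)   = Q(go, s) + b + pi * sgn(V(s))     (constant variant)
    W(nogo, s) = Q(nogo, s)

Choices follow a two-option softmax mixed with an irreducible lapse xi:

    p(a|s) = softmax(W)(a) * (1 - xi) + xi / 2.

Variants are declared by :class:`ModelSpec` flags; the conventional
five-model ladder of increasing complexity is in :data:`MODEL_LADDER`.
Parameters live in a constrained space (alpha, xi in (0,1); rho, pi > 0;
b real) with an unconstrained mirror (logit / log / identity) used by the
optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from pavbias import _kernel
from pavbias.conditions import CONDITION_INDEX, CONDITIONS, get_condition

__all__ = [
    "ModelSpec", "ParameterSet", "LearnerState", "MODEL_LADDER",
    "get_model", "register_model", "to_unconstrained", "to_constrained",
    "update_q", "update_v", "action_weights", "choice_probability",
    "session_log_likelihood", "replay_log_likelihood", "session_arrays",
]

_PAV_MODES = {"none": 0, "scaled": 1, "constant": 2}

# transform class per parameter name
_UNIT = frozenset({"alpha", "alpha_rew", "alpha_pun", "xi"})     # logit
_POSITIVE = frozenset({"rho", "rho_rew", "rho_pun", "pi"})       # log
_REAL = frozenset({"b"})                                         # identity


@dataclass(frozen=True)
class ModelSpec:
    """Structural flags selecting one member of the model family."""

    separate_sensitivities: bool = False
    has_noise: bool = False
    has_go_bias: bool = False
    pavlovian: str = "none"  # "none" | "scaled" | "constant"
    separate_learning_rates: bool = False

    def __post_init__(self):
        if self.pavlovian not in _PAV_MODES:
            raise ValueError(
                f"pavlovian must be one of {sorted(_PAV_MODES)}, "
                f"got {self.pavlovian!r}")

    @property
    def tracks_v(self) -> bool:
        return self.pavlovian != "none"

    @property
    def param_names(self) -> tuple:
        names = []
        if self.separate_learning_rates:
            names += ["alpha_rew", "alpha_pun"]
        else:
            names += ["alpha"]
        if self.separate_sensitivities:
            names += ["rho_rew", "rho_pun"]
        else:
            names += ["rho"]
        if self.has_noise:
            names += ["xi"]
        if self.has_go_bias:
            names += ["b"]
        if self.pavlovian != "none":
            names += ["pi"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def name(self) -> str:
        parts = ["RW"]
        if self.separate_sensitivities:
            parts[0] += "(rew/pun)"
        if self.separate_learning_rates:
            parts.append("dual-alpha")
        if self.has_noise:
            parts.append("noise")
        if self.has_go_bias:
            parts.append("bias")
        if self.pavlovian == "scaled":
            parts.append("pav")
        elif self.pavlovian == "constant":
            parts.append("pav(const)")
        return "+".join(parts)


@dataclass(frozen=True)
class ParameterSet:
    """Constrained-space parameter values for one model variant.

    Boundary values (alpha=0, xi=1, pi=0, ...) are accepted so degenerate
    agents can be simulated; mapping to the unconstrained space requires
    values strictly inside their domains.
    """

    spec: ModelSpec
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        expected = set(self.spec.param_names)
        got = set(self.values)
        if got != expected:
            raise ValueError(
                f"parameters {sorted(got)} do not match the active "
                f"parameters {sorted(expected)} of model {self.spec.name!r}")
        for name, v in self.values.items():
            v = float(v)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if name in _UNIT and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
            if name in _POSITIVE and v < 0.0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def get(self, name: str, default: float = 0.0) -> float:
        return float(self.values.get(name, default))

    # effective values with inactive parameters at their neutral settings
    @property
    def xi(self) -> float:
        return self.get("xi", 0.0)

    @property
    def go_bias(self) -> float:
        return self.get("b", 0.0)

    @property
    def pav_weight(self) -> float:
        return self.get("pi", 0.0)

    def alpha_for(self, outcome: int, is_win: bool) -> float:
        if not self.spec.separate_learning_rates:
            return self["alpha"]
        if outcome > 0:
            return self["alpha_rew"]
        if outcome < 0:
            return self["alpha_pun"]
        return self["alpha_rew"] if is_win else self["alpha_pun"]

    def rho_for(self, outcome: int) -> float:
        """Outcome sensitivity applied to this outcome (irrelevant at r=0)."""
        if not self.spec.separate_sensitivities:
            return self["rho"]
        return self["rho_rew"] if outcome >= 0 else self["rho_pun"]

    @property
    def unconstrained(self) -> np.ndarray:
        return to_unconstrained(self)

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in self.values.items()}


def to_unconstrained(params: ParameterSet) -> np.ndarray:
    """Map constrained parameter values to the optimizer's real vector.

    logit for (0,1) parameters, log for (0,inf) parameters, identity for b.
    """
    out = np.empty(params.spec.n_params)
    for i, name in enumerate(params.spec.param_names):
        v = params[name]
        if name in _UNIT:
            if not 0.0 < v < 1.0:
                raise ValueError(
                    f"{name}={v} is on the boundary; the logit transform "
                    "needs a value strictly inside (0, 1)")
            out[i] = math.log(v / (1.0 - v))
        elif name in _POSITIVE:
            if v <= 0.0:
                raise ValueError(
                    f"{name}={v} must be strictly positive for the log "
                    "transform")
            out[i] = math.log(v)
        else:
            out[i] = v
    return out


def to_constrained(vector: Sequence[float], spec: ModelSpec) -> ParameterSet:
    """Inverse of :func:`to_unconstrained`."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (spec.n_params,):
        raise ValueError(
            f"expected a vector of length {spec.n_params} for "
            f"{spec.name!r}, got shape {vector.shape}")
    values = {}
    for i, name in enumerate(spec.param_names):
        x = float(vector[i])
        if name in _UNIT:
            # numerically symmetric logistic
            values[name] = 0.5 * (1.0 + math.tanh(0.5 * x))
        elif name in _POSITIVE:
            values[name] = math.exp(x)
        else:
            values[name] = x
    return ParameterSet(spec, values)


# ---------------------------------------------------------------------------
# learning equations

@dataclass
class LearnerState:
    """Q (4 cues x [nogo, go]) and V (4 cues) value tables, initialized at 0."""

    q: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))
    v: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def copy(self) -> "LearnerState":
        return LearnerState(self.q.copy(), self.v.copy())


def update_q(q: float, r: int, alpha: float, rho_effective: float) -> float:
    """Delta-rule update of an action value toward rho * r."""
    return q + alpha * (rho_effective * r - q)


def update_v(v: float, r: int, alpha: float, rho_effective: float) -> float:
    """Delta-rule update of a cue's state value toward rho * r."""
    return v + alpha * (rho_effective * r - v)


def _sgn(x: float) -> float:
    if x > 0.0:
        return 1.0
    if x < 0.0:
        return -1.0
    return 0.0  # no Pavlovian pull before any valenced evidence


def action_weights(state_index: int, learner_state: LearnerState,
                   params: ParameterSet, spec: ModelSpec | None = None):
    """(W_go, W_nogo) for the shown cue under the variant's weight rule."""
    spec = spec or params.spec
    w_nogo = float(learner_state.q[state_index, 0])
    w_go = float(learner_state.q[state_index, 1])
    if spec.has_go_bias:
        w_go += params["b"]
    if spec.pavlovian == "scaled":
        w_go += params["pi"] * float(learner_state.v[state_index])
    elif spec.pavlovian == "constant":
        w_go += params["pi"] * _sgn(float(learner_state.v[state_index]))
    return w_go, w_nogo


def choice_probability(w_go: float, w_nogo: float, xi: float):
    """(p_go, p_nogo): two-option softmax mixed with a uniform lapse xi."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    d = w_go - w_nogo
    if d >= 0.0:
        p_go = 1.0 / (1.0 + math.exp(-d))
    else:
        e = math.exp(d)
        p_go = e / (1.0 + e)
    p_go = p_go * (1.0 - xi) + 0.5 * xi
    return p_go, 1.0 - p_go


def learn_from_trial(state: LearnerState, state_index: int, action: str,
                     outcome: int, params: ParameterSet) -> None:
    """Apply the Q and V updates for one observed trial, in place.

    Only the shown cue's entries change; V is updated regardless of the
    action taken (Pavlovian), Q only for the taken action (instrumental).
    """
    is_win = CONDITIONS[state_index].is_win
    alpha = params.alpha_for(outcome, is_win)
    rho = params.rho_for(outcome)
    a_col = 1 if action == "go" else 0
    state.q[state_index, a_col] = update_q(
        state.q[state_index, a_col], outcome, alpha, rho)
    state.v[state_index] = update_v(
        state.v[state_index], outcome, alpha, rho)


# ---------------------------------------------------------------------------
# session likelihood

def session_arrays(session):
    """Extract (cues, actions, outcomes, is_win) int arrays from a session.

    `session` is any object with an ordered `trials` iterable of records
    carrying `condition`, `action` and `outcome` fields.
    """
    trials = session.trials
    n = len(trials)
    if n == 0:
        raise ValueError("session contains no trials")
    cues = np.empty(n, dtype=np.int64)
    actions = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    is_win = np.empty(n, dtype=np.int64)
    for t, tr in enumerate(trials):
        cond = get_condition(tr.condition)
        cues[t] = CONDITION_INDEX[cond.name]
        if tr.action not in ("go", "nogo"):
            raise ValueError(f"trial {t}: unobserved action {tr.action!r}")
        actions[t] = 1 if tr.action == "go" else 0
        if tr.outcome not in (-1, 0, 1):
            raise ValueError(f"trial {t}: outcome {tr.outcome!r} not in "
                             "{-1, 0, 1}")
        outcomes[t] = tr.outcome
        is_win[t] = 1 if cond.is_win else 0
    return cues, actions, outcomes, is_win


def kernel_row(params: ParameterSet) -> np.ndarray:
    """Constrained parameters in the 7-slot kernel layout."""
    spec = params.spec
    if spec.separate_learning_rates:
        a_rew, a_pun = params["alpha_rew"], params["alpha_pun"]
    else:
        a_rew = a_pun = params["alpha"]
    if spec.separate_sensitivities:
        r_rew, r_pun = params["rho_rew"], params["rho_pun"]
    else:
        r_rew = r_pun = params["rho"]
    return np.array([a_rew, a_pun, r_rew, r_pun,
                     params.xi, params.go_bias, params.pav_weight])


def kernel_matrix(x_unconstrained: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Vectorized unconstrained (n, k) -> kernel-layout (n, 7) mapping."""
    x = np.atleast_2d(np.asarray(x_unconstrained, dtype=float))
    names = spec.param_names
    cols = {}
    for i, name in enumerate(names):
        if name in _UNIT:
            cols[name] = 0.5 * (1.0 + np.tanh(0.5 * x[:, i]))
        elif name in _POSITIVE:
            # cap keeps extreme optimizer/MC probes finite (exp(60) ~ 1e26)
            cols[name] = np.exp(np.minimum(x[:, i], 60.0))
        else:
            cols[name] = x[:, i]
    n = x.shape[0]
    zeros = np.zeros(n)
    a_rew = cols.get("alpha_rew", cols.get("alpha"))
    a_pun = cols.get("alpha_pun", cols.get("alpha"))
    r_rew = cols.get("rho_rew", cols.get("rho"))
    r_pun = cols.get("rho_pun", cols.get("rho"))
    return np.column_stack([
        a_rew, a_pun, r_rew, r_pun,
        cols.get("xi", zeros), cols.get("b", zeros), cols.get("pi", zeros)])


def loglik_arrays(x_unconstrained, arrays, spec: ModelSpec) -> float:
    """Session log-likelihood from pre-extracted arrays (hot path)."""
    cues, actions, outcomes, is_win = arrays
    row = kernel_matrix(x_unconstrained, spec)[0]
    return float(_kernel.replay_loglik(
        cues, actions, outcomes, is_win,
        row[0], row[1], row[2], row[3], row[4], row[5], row[6],
        _PAV_MODES[spec.pavlovian]))


def loglik_arrays_batch(x_matrix, arrays, spec: ModelSpec) -> np.ndarray:
    """Log-likelihood of one session at many unconstrained vectors."""
    cues, actions, outcomes, is_win = arrays
    theta = kernel_matrix(x_matrix, spec)
    return _kernel.replay_loglik_batch(
        cues, actions, outcomes, is_win, theta, _PAV_MODES[spec.pavlovian])


def session_log_likelihood(params_unconstrained, session,
                           spec: ModelSpec) -> float:
    """Log-likelihood of a session's choices at an unconstrained vector.

    Replays the trial sequence: per trial the probability of the observed
    action is accumulated, then Q and V are updated with the observed
    action and outcome.
    """
    return loglik_arrays(np.asarray(params_unconstrained, dtype=float),
                         session_arrays(session), spec)


def replay_log_likelihood(params: ParameterSet, session) -> float:
    """Reference log-likelihood composed from the public primitives.

    Computes the same quantity as :func:`session_log_likelihood` by
    stepping `action_weights` -> `choice_probability` -> `learn_from_trial`
    in pure Python. Accepts boundary parameter values (e.g. xi = 1).
    """
    trials = session.trials
    if len(trials) == 0:
        raise ValueError("session contains no trials")
    state = LearnerState()
    ll = 0.0
    for tr in trials:
        cond = get_condition(tr.condition)
        s = CONDITION_INDEX[cond.name]
        w_go, w_nogo = action_weights(s, state, params)
        p_go, p_nogo = choice_probability(w_go, w_nogo, params.xi)
        p = p_go if tr.action == "go" else p_nogo
        ll += math.log(max(p, _kernel.PROB_FLOOR))
        learn_from_trial(state, s, tr.action, tr.outcome, params)
    return ll


# ---------------------------------------------------------------------------
# model registry

MODEL_LADDER = (
    ModelSpec(),
    ModelSpec(has_noise=True),
    ModelSpec(has_noise=True, has_go_bias=True),
    ModelSpec(separate_sensitivities=True, has_noise=True, has_go_bias=True,
              pavlovian="scaled"),
    ModelSpec(separate_sensitivities=True, has_noise=True, has_go_bias=True,
              pavlovian="constant"),
)
"""Five-variant ladder of increasing complexity; the last row is the
winning model of this paradigm's literature."""

WINNING_MODEL = MODEL_LADDER[-1]

_REGISTRY = {spec.name: spec for spec in MODEL_LADDER}


def register_model(spec: ModelSpec) -> None:
    _REGISTRY[spec.name] = spec


def get_model(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered models: "
            f"{sorted(_REGISTRY)}") from None
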