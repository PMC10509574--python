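"""Model-free behavioural statistics for the Go-NoGo task.

Exclusion rules, per-condition accuracies, the linear descriptive estimates
of Pavlovian and Go bias,

    Pavlovian bias = (G2W + NG2AP) - (NG2W + G2AP)
    Go bias        = (G2W + G2AP) - (NG2AP + NG2W),

and the inferential battery: repeated-measures ANOVAs built from 1-df
within-subject orthogonal contrasts (so each effect's F on (1, n-1) df is
the squared paired t of its contrast), paired t-tests, and variance-ratio
F-tests between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pavbias.conditions import CONDITIONS, get_condition

__all__ = [
    "ConditionAccuracy", "ExclusionDecision", "apply_exclusions",
    "condition_accuracy", "descriptive_pavlovian_bias", "descriptive_go_bias",
    "rm_anova_2x2", "rm_anova_2x2x2", "paired_t", "variance_ratio",
    "accuracy_table",
]

CONDITION_NAMES = tuple(c.name for c in CONDITIONS)  # G2W, G2AP, NG2W, NG2AP


@dataclass
class ConditionAccuracy:
    """Proportion of correct Go/NoGo decisions per condition."""

    subject_id: str
    session: int
    accuracy: dict  # condition name -> proportion in [0, 1]

    def __getitem__(self, name: str) -> float:
        return self.accuracy[name]


@dataclass
class ExclusionDecision:
    subject_id: str
    session: int
    localization_error_rate: float | None  # None when the subject never went
    go_count: int
    total_trials: int
    excluded: bool
    reason: str  # "none" | "localization" | "uniform_response"


def _localization_error_rate(session):
    presses = [t for t in session.trials if t.response in ("left", "right")]
    if not presses:
        return None, 0
    wrong = sum(1 for t in presses if t.response != t.target_side)
    return wrong / len(presses), len(presses)


def apply_exclusions(sessions, localization_threshold: float = 0.45):
    """Drop inattentive and uniform responders; report every decision.

    A subject-session is excluded when (i) more than `localization_threshold`
    of its presses land on the wrong side of the target, or (ii) the subject
    goes on every trial or presses nothing at all (uniform responders carry
    no instrumental signal; never-pressing subjects also have an undefined
    localization rate). Returns ``(kept_sessions, decisions)``.
    """
    kept, decisions = [], []
    for session in sessions:
        n = session.n_trials
        go_count = sum(1 for t in session.trials if t.action == "go")
        loc_rate, _ = _localization_error_rate(session)
        if go_count == 0 or go_count == n:
            excluded, reason = True, "uniform_response"
        elif loc_rate is not None and loc_rate > localization_threshold:
            excluded, reason = True, "localization"
        else:
            excluded, reason = False, "none"
        decisions.append(ExclusionDecision(
            subject_id=session.subject_id, session=session.session,
            localization_error_rate=loc_rate, go_count=go_count,
            total_trials=n, excluded=excluded, reason=reason))
        if not excluded:
            kept.append(session)
    return kept, decisions


def condition_accuracy(session) -> ConditionAccuracy:
    """Mean correctness of the Go/NoGo decision, per condition."""
    totals = {name: 0 for name in CONDITION_NAMES}
    hits = {name: 0 for name in CONDITION_NAMES}
    for t in session.trials:
        cond = get_condition(t.condition)
        if t.action is None:
            raise ValueError("session has unobserved trials")
        totals[cond.name] += 1
        hits[cond.name] += int(t.action == cond.correct_action)
    empty = [n for n in CONDITION_NAMES if totals[n] == 0]
    if empty:
        raise ValueError(f"no trials for condition(s) {empty}; accuracy "
                         "undefined")
    return ConditionAccuracy(
        subject_id=session.subject_id, session=session.session,
        accuracy={n: hits[n] / totals[n] for n in CONDITION_NAMES})


def descriptive_pavlovian_bias(acc: ConditionAccuracy) -> float:
    """(G2W + NG2AP) - (NG2W + G2AP); range [-2, 2]."""
    a = acc.accuracy
    return (a["G2W"] + a["NG2AP"]) - (a["NG2W"] + a["G2AP"])


def descriptive_go_bias(acc: ConditionAccuracy) -> float:
    """(G2W + G2AP) - (NG2AP + NG2W); range [-2, 2]."""
    a = acc.accuracy
    return (a["G2W"] + a["G2AP"]) - (a["NG2AP"] + a["NG2W"])


def accuracy_table(sessions) -> pd.DataFrame:
    """Tidy frame: one row per subject-session, accuracy columns + biases."""
    rows = []
    for s in sessions:
        acc = condition_accuracy(s)
        row = {"subject_id": s.subject_id, "session": s.session}
        row.update(acc.accuracy)
        row["pavlovian_bias"] = descriptive_pavlovian_bias(acc)
        row["go_bias"] = descriptive_go_bias(acc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# within-subject contrast ANOVA

def _contrast_test(scores: np.ndarray):
    """Paired-t of a per-subject contrast; returns (F, df, p)."""
    n = scores.size
    if np.allclose(np.var(scores, ddof=1), 0.0):
        if np.allclose(scores.mean(), 0.0):
            return 0.0, (1, n - 1), 1.0  # no effect, no spread
        raise ValueError("contrast scores are a nonzero constant; "
                         "F is undefined")
    t, _ = stats.ttest_1samp(scores, 0.0)
    f = float(t * t)
    p = float(stats.f.sf(f, 1, n - 1))
    return f, (1, n - 1), p


def _cells_to_array(accuracies, cols):
    if isinstance(accuracies, pd.DataFrame):
        missing = [c for c in cols if c not in accuracies.columns]
        if missing:
            raise ValueError(f"missing condition columns: {missing}")
        arr = accuracies[list(cols)].to_numpy(dtype=float)
    else:
        arr = np.asarray(accuracies, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(cols):
        raise ValueError(f"expected an (n_subjects, {len(cols)}) table")
    if arr.shape[0] < 2:
        raise ValueError("ANOVA needs at least 2 subjects")
    if np.isnan(arr).any():
        raise ValueError("accuracy table contains missing cells")
    return arr


def rm_anova_2x2(accuracies) -> dict:
    """Within-subject 2 (action) x 2 (valence) ANOVA on condition accuracies.

    `accuracies` is an (n, 4) array or DataFrame with columns
    G2W, G2AP, NG2W, NG2AP. Each effect is the paired t-test of its
    orthogonal contrast, reported as F on (1, n-1) df:
    action = Go - NoGo conditions, valence = win - punishment conditions,
    interaction = congruent - incongruent (the Pavlovian crossover).
    Returns {effect: {"F": F, "df": (1, n-1), "p": p}}.
    """
    arr = _cells_to_array(accuracies, CONDITION_NAMES)
    g2w, g2ap, ng2w, ng2ap = arr.T
    contrasts = {
        "action": (g2w + g2ap) - (ng2w + ng2ap),
        "valence": (g2w + ng2w) - (g2ap + ng2ap),
        "action:valence": (g2w + ng2ap) - (ng2w + g2ap),
    }
    out = {}
    for effect, scores in contrasts.items():
        f, df, p = _contrast_test(scores)
        out[effect] = {"F": f, "df": df, "p": p}
    return out


_SESSION_COLS = tuple(f"{c}_s{s}" for s in (1, 2) for c in CONDITION_NAMES)


def rm_anova_2x2x2(accuracies) -> dict:
    """2 (action) x 2 (valence) x 2 (session) within-subject ANOVA.

    `accuracies` is an (n, 8) array or DataFrame with columns
    G2W_s1 ... NG2AP_s1, G2W_s2 ... NG2AP_s2. Seven orthogonal 1-df
    contrasts (three main effects, three two-way interactions, one
    three-way), each tested as a paired t / F on (1, n-1).
    """
    arr = _cells_to_array(accuracies, _SESSION_COLS)
    # per-cell signs in the order of _SESSION_COLS
    action = np.array([1, 1, -1, -1])
    valence = np.array([1, -1, 1, -1])
    ones = np.ones(4, dtype=int)
    half = {"action": action, "valence": valence,
            "action:valence": action * valence}
    effects = {}
    for name, c in half.items():
        effects[name] = np.concatenate([c, c])
        effects[f"session:{name}"] = np.concatenate([-c, c])
    effects["session"] = np.concatenate([-ones, ones])
    out = {}
    for effect in ("action", "valence", "session", "action:valence",
                   "session:action", "session:valence",
                   "session:action:valence"):
        out[effect] = effects[effect]
    results = {}
    for effect, c in out.items():
        scores = arr @ c
        f, df, p = _contrast_test(scores)
        results[effect] = {"F": f, "df": df, "p": p}
    return results


def paired_t(x, y):
    """Two-tailed paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    if np.allclose(np.var(d, ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, x.size - 1, 1.0  # identical samples: no effect
        raise ValueError("differences are a nonzero constant; "
                         "t is undefined")
    t, p = stats.ttest_rel(x, y)
    return float(t), x.size - 1, float(p)


def variance_ratio(x, y, two_tailed: bool = False):
    """F-test for equality of variances; returns (F, (df1, df2), p).

    F = var(x) / var(y) with df (n-1, m-1); the p-value is the one-tailed
    upper tail P(F' > F) by default (the convention used when comparing
    session variances), with a two-tailed option.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("variance_ratio needs n >= 2 in each sample")
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vy == 0.0:
        raise ValueError("second sample has zero variance")
    f = float(vx / vy)
    df = (x.size - 1, y.size - 1)
    p = float(stats.f.sf(f, *df))
    if two_tailed:
        p = float(2.0 * min(p, 1.0 - p))
    return f, df, p
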