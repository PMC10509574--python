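"""Test-retest reliability via Pearson correlations with Fisher-z intervals.

A measure's reliability is the Pearson correlation of its session-1 and
session-2 values over subjects present in both sessions. Confidence
intervals use the Fisher z-transform,

    atanh(r) +/- z_crit / sqrt(n - 3),

mapped back through tanh; the same interval around an assumed correlation
gives the precision a planned sample size affords. Strictly positive model
parameters (pi, rho_rew, rho_pun) are correlated on the log scale, the Go
bias, learning rate and lapse on their raw scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pavbias.fitting import analysis_scale

__all__ = ["pearson_r", "precision_at_n", "reliability_report",
           "consistency_check", "LOG_SCALE_PARAMS"]

LOG_SCALE_PARAMS = frozenset({"pi", "rho", "rho_rew", "rho_pun"})


def _fisher_ci(r: float, n: int, level: float = 0.95):
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    # clip keeps r = +/-1 (degenerate but legal input) finite in z space
    z = np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    half = z_crit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_r(x, y, level: float = 0.95):
    """Pearson r with two-tailed p and a Fisher-z confidence interval.

    Returns ``(r, p, (ci_low, ci_high))``. The p-value is the usual
    t-based test of r = 0 on n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r needs two equal-length 1-d vectors")
    if x.size < 4:
        raise ValueError("pearson_r needs n >= 4 for a confidence interval")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs contain non-finite values")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("an input has zero variance; r is undefined")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p, _fisher_ci(r, x.size, level)


def precision_at_n(r_assumed: float, n: int, level: float = 0.95):
    """Fisher-z interval a sample of size n affords around an assumed r.

    Planning calculation: e.g. at n = 114 an assumed r of 0.15 affords
    roughly (-0.035, 0.33) and an assumed 0.70 affords (0.59, 0.78).
    """
    if not -1.0 < r_assumed < 1.0:
        raise ValueError("r_assumed must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    return _fisher_ci(float(r_assumed), int(n), level)


def _join_sessions(m1: pd.DataFrame, m2: pd.DataFrame):
    common = m1.index.intersection(m2.index)
    dropped = (len(m1) - len(common)) + (len(m2) - len(common))
    if dropped:
        import logging
        logging.getLogger(__name__).info(
            "reliability: %d subject-session rows without a partner were "
            "dropped (inner join on subject_id)", dropped)
    return m1.loc[common], m2.loc[common]


def reliability_report(session1_measures: pd.DataFrame,
                       session2_measures: pd.DataFrame,
                       measures=None, level: float = 0.95) -> pd.DataFrame:
    """Per-measure test-retest correlation table.

    Inputs are DataFrames indexed by subject_id with one column per measure
    (condition accuracies, descriptive biases, fitted parameters); only
    subjects present in both sessions enter. Positive-definite parameters
    are log-transformed first. Returns a DataFrame with columns
    measure, n, r, p, ci_low, ci_high, scale.
    """
    m1, m2 = _join_sessions(session1_measures, session2_measures)
    if measures is None:
        measures = [c for c in m1.columns if c in m2.columns]
    rows = []
    for name in measures:
        x = m1[name].to_numpy(dtype=float)
        y = m2[name].to_numpy(dtype=float)
        scale = "raw"
        if name in LOG_SCALE_PARAMS:
            x, y = np.log(x), np.log(y)
            scale = "log"
        r, p, (lo, hi) = pearson_r(x, y, level)
        rows.append({"measure": name, "n": x.size, "r": r, "p": p,
                     "ci_low": lo, "ci_high": hi, "scale": scale})
    return pd.DataFrame(rows)


def consistency_check(estimates: pd.DataFrame,
                      descriptive: pd.DataFrame, level: float = 0.95):
    """Within-session agreement of model-based and descriptive bias measures.

    Correlates fitted log(pi) with the descriptive Pavlovian-bias composite
    and fitted b with the descriptive Go-bias composite, over the subjects
    shared by both frames (indexed by subject_id). Returns a dict
    {"pavlovian": (r, p, ci), "go": (r, p, ci)} with entries only for the
    parameters present in `estimates`.
    """
    est, desc = _join_sessions(estimates, descriptive)
    est = analysis_scale(est)
    out = {}
    if "pi" in est.columns and "pavlovian_bias" in desc.columns:
        out["pavlovian"] = pearson_r(est["pi"], desc["pavlovian_bias"], level)
    if "b" in est.columns and "go_bias" in desc.columns:
        out["go"] = pearson_r(est["b"], desc["go_bias"], level)
    if not out:
        raise ValueError("no overlapping bias measures to correlate")
    return out
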