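"""Hierarchical empirical-Bayes fitting and model comparison.

Each subject's parameters (unconstrained space) get a Gaussian group prior.
Fitting alternates:

* E-step: per-subject MAP estimation by quasi-Newton optimization of
  log-likelihood + log-prior, with the posterior curvature taken from a
  finite-difference Hessian at the mode (Laplace approximation);
* M-step: the prior mean is updated to the mean of the posterior modes and
  the prior variance to the Laplace second moments
  (mode^2 + diagonal of the inverse Hessian) minus the squared mean,
  floored to keep the prior from collapsing.

The loop stops when no hyperparameter moves by more than `em_tol`.

Models are compared by the integrated BIC: per subject the likelihood is
integrated over the fitted group prior by Monte-Carlo (log-mean-exp over
prior draws), and the summed log evidence is penalized by
(number of hyperparameters) * log(total number of choices):

    iBIC = -2 * sum_i log p(data_i | prior) + 2k * log(N_choices).

Lower is better. `parameter_recovery` closes the loop: simulate a cohort
with known parameters, refit, and correlate truth with estimates.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from pavbias import models as M
from pavbias._kernel import replay_loglik_batch
from pavbias.task import CohortConfig, generate_cohort

__all__ = [
    "GroupPrior", "SubjectPosterior", "GroupFit", "FitOptions",
    "RecoveryResult", "fit_map_subject", "em_fit", "ibic", "compare_models",
    "parameter_recovery",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupPrior:
    """Independent Gaussian prior per unconstrained parameter."""

    names: tuple
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != (len(self.names),) or \
                self.var.shape != (len(self.names),):
            raise ValueError("prior mean/var must match the parameter names")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.var)

    def log_pdf(self, x: np.ndarray) -> float:
        z = (np.asarray(x, dtype=float) - self.mean)
        return float(-0.5 * np.sum(z * z / self.var
                                   + np.log(2.0 * np.pi * self.var)))


@dataclass
class SubjectPosterior:
    mode: np.ndarray
    hessian: np.ndarray           # of the negative log posterior, at the mode
    log_posterior_at_mode: float
    converged: bool

    @property
    def laplace_var(self) -> np.ndarray:
        """Diagonal of the inverse (regularized) Hessian."""
        cov = np.linalg.inv(self.hessian)
        return np.clip(np.diag(cov), 0.0, None)


@dataclass
class FitOptions:
    """Tunable knobs of the EM fit, with the package defaults."""

    n_restarts: int = 5
    em_tol: float = 1e-3
    max_em_iter: int = 100
    n_mc_samples: int = 10_000
    init_mean: float = 0.0
    init_var: float = 6.25
    var_floor: float = 1e-6
    hessian_step: float = 1e-3
    penalty_obs: str = "choices"   # "choices" | "subjects"


@dataclass
class GroupFit:
    model_spec: M.ModelSpec
    prior: GroupPrior
    posteriors: list
    n_em_iterations: int
    converged: bool
    subject_ids: list
    n_obs: int
    ibic: float | None = None

    @property
    def estimates(self) -> pd.DataFrame:
        """Per-subject MAP estimates on the constrained scale."""
        rows = [M.to_constrained(p.mode, self.model_spec).as_dict()
                for p in self.posteriors]
        return pd.DataFrame(rows, index=pd.Index(self.subject_ids,
                                                 name="subject_id"))

    @property
    def estimates_unconstrained(self) -> pd.DataFrame:
        return pd.DataFrame([p.mode for p in self.posteriors],
                            columns=list(self.model_spec.param_names),
                            index=pd.Index(self.subject_ids,
                                           name="subject_id"))


# ---------------------------------------------------------------------------
# subject-level MAP + Laplace

def _numerical_hessian(f, x, rel_step):
    """Central finite-difference Hessian of scalar f at x."""
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fij = (f(x + ei + ej) - f(x + ei - ej)
                   - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = fij
    return hess


def _regularize_pd(hess):
    """Add eps*I until the matrix admits a Cholesky factorization."""
    hess = 0.5 * (hess + hess.T)
    eps = 0.0
    step = 1e-6 * max(1.0, float(np.max(np.abs(np.diag(hess)))))
    k = hess.shape[0]
    for _ in range(60):
        try:
            np.linalg.cholesky(hess + eps * np.eye(k))
            if eps > 0.0:
                logger.warning(
                    "Hessian not positive definite; regularized with "
                    "eps=%.3g * I", eps)
            return hess + eps * np.eye(k)
        except np.linalg.LinAlgError:
            eps = step if eps == 0.0 else eps * 4.0
    raise np.linalg.LinAlgError("could not regularize Hessian")


def _map_from_arrays(arrays, spec, prior, n_restarts, rng, x0=None,
                     hessian_step=1e-3):
    def neg_log_post(x):
        return -(M.loglik_arrays(x, arrays, spec) + prior.log_pdf(x))

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(prior.mean.copy())
    while len(starts) < max(1, n_restarts):
        starts.append(prior.mean + prior.sd * rng.standard_normal(
            len(prior.names)))

    best_x, best_f, any_success = None, np.inf, False
    for s in starts:
        res = optimize.minimize(neg_log_post, s, method="L-BFGS-B")
        any_success = any_success or bool(res.success)
        # never do worse than the start point itself
        for cand_x, cand_f in ((res.x, float(res.fun)),
                               (s, neg_log_post(s))):
            if np.isfinite(cand_f) and cand_f < best_f:
                best_x, best_f = np.asarray(cand_x, dtype=float), cand_f

    hess = _numerical_hessian(neg_log_post, best_x, hessian_step)
    hess = _regularize_pd(hess)
    return SubjectPosterior(mode=best_x, hessian=hess,
                            log_posterior_at_mode=-best_f,
                            converged=any_success)


def fit_map_subject(session, spec: M.ModelSpec, prior: GroupPrior,
                    n_restarts: int = 5, seed: int = 0,
                    x0=None, hessian_step: float = 1e-3) -> SubjectPosterior:
    """MAP estimate and Laplace curvature for one subject-session.

    Maximizes log-likelihood plus Gaussian log-prior in unconstrained space
    from `n_restarts` starts (the prior mean plus prior-scaled jitter); the
    returned Hessian is of the negative log posterior at the mode,
    regularized to positive definiteness if needed.
    """
    arrays = M.session_arrays(session)
    rng = np.random.default_rng(seed)
    return _map_from_arrays(arrays, spec, prior, n_restarts, rng, x0=x0,
                            hessian_step=hessian_step)


# ---------------------------------------------------------------------------
# group-level EM

def _subject_rng(seed, em_iter, arrays):
    # keyed on the data content so identical sessions get identical restarts
    crc = zlib.crc32(b"".join(a.tobytes() for a in arrays))
    return np.random.default_rng([seed & 0x7FFFFFFF, em_iter, crc])


def em_fit(cohort, spec: M.ModelSpec, options: FitOptions | None = None,
           seed: int = 0) -> GroupFit:
    """Empirical-Bayes EM fit of one model to a list of sessions.

    `cohort` is a list of :class:`~pavbias.task.SessionData` (one per
    subject). Hyperparameters start at N(0, 6.25) for every parameter and
    are updated by Laplace moment-matching until the largest absolute
    change falls below `options.em_tol`.
    """
    options = options or FitOptions()
    if len(cohort) < 2:
        raise ValueError("em_fit needs at least 2 subjects")
    arrays_list = [M.session_arrays(s) for s in cohort]
    subject_ids = [getattr(s, "subject_id", str(i))
                   for i, s in enumerate(cohort)]
    names = spec.param_names
    k = len(names)
    prior = GroupPrior(names,
                       np.full(k, options.init_mean),
                       np.full(k, options.init_var))
    warm = [None] * len(cohort)
    posteriors = []
    converged = False
    n_iter = 0
    for em_iter in range(options.max_em_iter):
        n_iter = em_iter + 1
        posteriors = []
        for i, arrays in enumerate(arrays_list):
            rng = _subject_rng(seed, em_iter, arrays)
            n_restarts = options.n_restarts if em_iter == 0 else 1
            post = _map_from_arrays(arrays, spec, prior, n_restarts, rng,
                                    x0=warm[i],
                                    hessian_step=options.hessian_step)
            posteriors.append(post)
            warm[i] = post.mode
        modes = np.array([p.mode for p in posteriors])
        lap_var = np.array([p.laplace_var for p in posteriors])
        new_mean = modes.mean(axis=0)
        second_moment = (modes ** 2 + lap_var).mean(axis=0)
        new_var = np.maximum(second_moment - new_mean ** 2,
                             options.var_floor)
        delta = max(float(np.max(np.abs(new_mean - prior.mean))),
                    float(np.max(np.abs(new_var - prior.var))))
        prior = GroupPrior(names, new_mean, new_var)
        if delta < options.em_tol:
            converged = True
            break
    n_obs = int(sum(a[0].size for a in arrays_list))
    return GroupFit(model_spec=spec, prior=prior, posteriors=posteriors,
                    n_em_iterations=n_iter, converged=converged,
                    subject_ids=subject_ids, n_obs=n_obs)


def ibic(group_fit: GroupFit, cohort, n_mc_samples: int = 10_000,
         seed: int = 0, penalty_obs: str = "choices") -> float:
    """Integrated BIC of a fitted model on its cohort.

    Each subject's evidence is the likelihood averaged over `n_mc_samples`
    draws from the fitted group prior (log-mean-exp, so zero-likelihood
    draws are harmless); the penalty counts two hyperparameters (mean and
    variance) per model parameter against the total number of choices.
    """
    spec = group_fit.model_spec
    prior = group_fit.prior
    rng = np.random.default_rng(seed)
    k = len(prior.names)
    draws = prior.mean + prior.sd * rng.standard_normal((n_mc_samples, k))
    theta = M.kernel_matrix(draws, spec)
    total = 0.0
    n_choices = 0
    pav_mode = M._PAV_MODES[spec.pavlovian]
    for session in cohort:
        cues, actions, outcomes, is_win = M.session_arrays(session)
        lls = replay_loglik_batch(cues, actions, outcomes, is_win,
                                  theta, pav_mode)
        total += float(logsumexp(lls) - np.log(n_mc_samples))
        n_choices += cues.size
    n_pen = n_choices if penalty_obs == "choices" else len(cohort)
    value = -2.0 * total + 2.0 * k * np.log(n_pen)
    group_fit.ibic = float(value)
    return float(value)


def compare_models(cohort, specs, options: FitOptions | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Fit each candidate model and rank them by iBIC (ascending).

    A model whose fit raises is recorded with NaN iBIC and the comparison
    proceeds with the rest.
    """
    options = options or FitOptions()
    rows = []
    for j, spec in enumerate(specs):
        try:
            fit = em_fit(cohort, spec, options, seed=seed)
            value = ibic(fit, cohort, n_mc_samples=options.n_mc_samples,
                         seed=seed + 1, penalty_obs=options.penalty_obs)
            rows.append({"model": spec.name, "n_params": spec.n_params,
                         "ibic": value, "em_iterations": fit.n_em_iterations,
                         "converged": fit.converged, "error": ""})
        except Exception as exc:  # noqa: BLE001 - comparison must proceed
            logger.warning("fit of %s failed: %s", spec.name, exc)
            rows.append({"model": spec.name, "n_params": spec.n_params,
                         "ibic": np.nan, "em_iterations": 0,
                         "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values(
        "ibic", na_position="last").reset_index(drop=True)
    table["delta_ibic"] = table["ibic"] - table["ibic"].min()
    return table


# ---------------------------------------------------------------------------
# parameter recovery

@dataclass
class RecoveryResult:
    true_params: pd.DataFrame       # constrained scale
    estimates: pd.DataFrame         # constrained scale
    r: dict                         # per-parameter Pearson r, analysis scale
    group_fit: GroupFit
    scale_note: str = ("correlations on log scale for (0, inf) parameters, "
                       "raw otherwise")


def analysis_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Log-transform the strictly positive parameters for correlation."""
    out = df.copy()
    for col in out.columns:
        if col in M._POSITIVE:
            out[col] = np.log(out[col])
    return out


def parameter_recovery(spec: M.ModelSpec, prior: dict, n_subjects: int,
                       seed: int = 0, options: FitOptions | None = None,
                       **cohort_kwargs) -> RecoveryResult:
    """Simulate -> refit -> correlate truth with estimates, per parameter.

    `prior` maps parameter names to unconstrained (mean, sd) generating
    values. Correlations use the log scale for positive parameters.
    """
    if n_subjects < 3:
        raise ValueError("parameter recovery needs at least 3 subjects for "
                         "a meaningful correlation")
    cfg = CohortConfig(n_subjects=n_subjects, model_spec=spec, prior=prior,
                       n_sessions=1, seed=seed, **cohort_kwargs)
    cohort = generate_cohort(cfg)
    sessions = [subj.sessions[1] for subj in cohort]
    fit = em_fit(sessions, spec, options, seed=seed)
    true_df = pd.DataFrame(
        [subj.true_params[1].as_dict() for subj in cohort],
        index=pd.Index([s.subject_id for s in cohort], name="subject_id"))
    est_df = fit.estimates
    t_scaled = analysis_scale(true_df)
    e_scaled = analysis_scale(est_df)
    r = {name: float(np.corrcoef(t_scaled[name], e_scaled[name])[0, 1])
         for name in spec.param_names}
    return RecoveryResult(true_params=true_df, estimates=est_df, r=r,
                          group_fit=fit)
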