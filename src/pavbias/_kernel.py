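"""Numba-compiled trial-replay likelihood kernels.

The session log-likelihood replays a subject's trial sequence under the
Rescorla-Wagner action-value model: per trial it evaluates the probability of
the observed Go/NoGo choice from the current action weights, then applies the
delta-rule updates to the shown cue's Q and V entries. Hierarchical fitting
evaluates this function millions of times (quasi-Newton restarts,
finite-difference gradients and Hessians, Monte-Carlo integration for the
integrated BIC), so the replay loop is JIT-compiled. The pure-Python
composition of the public primitives in :mod:`pavbias.models`
(`replay_log_likelihood`) computes the identical quantity and serves as the
reference implementation.

Kernel parameter layout (constrained space), one row per parameter vector::

    [alpha_rew, alpha_pun, rho_rew, rho_pun, xi, b, pi]

Models with a single learning rate or sensitivity pass the same value in both
slots; inactive parameters are passed as xi=0, b=0, pi=0. ``pav_mode`` is
0 (no Pavlovian term), 1 (weight adds pi*V), or 2 (weight adds pi*sgn(V)).
"""

import numpy as np
from numba import njit

N_STATES = 4
PROB_FLOOR = 1e-12  # only binding when xi == 0; otherwise p >= xi/2


@njit(cache=True)
def replay_loglik(cues, actions, outcomes, is_win,
                  alpha_rew, alpha_pun, rho_rew, rho_pun, xi, b, pi,
                  pav_mode):
    """Log-likelihood of one session's Go/NoGo choices.

    cues: int array of state indices (0..3); actions: 1=Go, 0=NoGo;
    outcomes: -1/0/+1; is_win: 1 for win-valence cues (used only to pick the
    learning rate on neutral outcomes when rates are split by valence).
    """
    q_go = np.zeros(N_STATES)
    q_nogo = np.zeros(N_STATES)
    v = np.zeros(N_STATES)
    ll = 0.0
    for t in range(cues.shape[0]):
        s = cues[t]
        a = actions[t]
        r = outcomes[t]

        w_go = q_go[s] + b
        if pav_mode == 1:
            w_go += pi * v[s]
        elif pav_mode == 2:
            if v[s] > 0.0:
                w_go += pi
            elif v[s] < 0.0:
                w_go -= pi
        d = w_go - q_nogo[s]
        # stable two-option softmax mixed with the uniform lapse
        if d >= 0.0:
            p_go = 1.0 / (1.0 + np.exp(-d))
        else:
            e = np.exp(d)
            p_go = e / (1.0 + e)
        p_go = p_go * (1.0 - xi) + 0.5 * xi
        p = p_go if a == 1 else 1.0 - p_go
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        ll += np.log(p)

        if r > 0:
            rho = rho_rew
            alpha = alpha_rew
        elif r < 0:
            rho = rho_pun
            alpha = alpha_pun
        else:
            rho = 0.0  # rho multiplies r; irrelevant on neutral outcomes
            alpha = alpha_rew if is_win[t] == 1 else alpha_pun
        target = rho * r
        if a == 1:
            q_go[s] += alpha * (target - q_go[s])
        else:
            q_nogo[s] += alpha * (target - q_nogo[s])
        v[s] += alpha * (target - v[s])
    return ll


@njit(cache=True)
def replay_loglik_batch(cues, actions, outcomes, is_win, theta, pav_mode):
    """Vectorized replay over a (n, 7) matrix of kernel parameter rows."""
    n = theta.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = replay_loglik(
            cues, actions, outcomes, is_win,
            theta[i, 0], theta[i, 1], theta[i, 2], theta[i, 3],
            theta[i, 4], theta[i, 5], theta[i, 6], pav_mode)
    return out
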