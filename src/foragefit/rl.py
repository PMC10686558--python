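"""Rescorla-Wagner model with forgetting, and the RL expertise index.

The model keeps separate action values for the chosen and unchosen port.
On each trial the chosen value moves toward the outcome with a learning
rate that differs between rewarded and unrewarded trials, while the
unchosen value decays toward zero with a forgetting rate:

    Q_ch  <- Q_ch + alpha_rew * (R - Q_ch)   if R = 1
    Q_ch  <- Q_ch + alpha_unr * (R - Q_ch)   if R = 0
    Q_unch <- (1 - delta) * Q_unch

and the left-choice probability is a softmax on the value difference,

    P_L = 1 / (1 + exp(-beta_dq * (beta0 + Q_L - Q_R))).

The RL index is the per-trial log-likelihood improvement of this model
over a bias-only null; sessions at or above 0.08 are flagged "expert".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._logistic import PROB_CLIP
from .session import SessionTable

EXPERT_RL_INDEX = 0.08

# parameter bounds for maximum-likelihood search
RL_BOUNDS = [(0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 20.0), (-5.0, 5.0)]


@dataclass
class RLParams:
    alpha_rew: float
    alpha_unr: float
    delta: float
    beta_dq: float
    beta0: float

    def __post_init__(self):
        for name in ("alpha_rew", "alpha_unr", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_rew, self.alpha_unr, self.delta, self.beta_dq, self.beta0]
        )

    @classmethod
    def from_array(cls, x) -> "RLParams":
        return cls(*(float(v) for v in x))


@dataclass
class RLFit:
    params: RLParams
    loglik: float
    rl_index: float
    n_trials: int
    expert: bool = field(init=False)

    def __post_init__(self):
        self.expert = bool(self.rl_index >= EXPERT_RL_INDEX)


def q_update(
    q_ch: float, q_unch: float, reward: int, params: RLParams
) -> tuple[float, float]:
    """One value update: chosen value toward the outcome, unchosen decays."""
    alpha = params.alpha_rew if reward == 1 else params.alpha_unr
    return q_ch + alpha * (reward - q_ch), (1.0 - params.delta) * q_unch


def rl_choice_prob(q_left: float, q_right: float, params: RLParams) -> float:
    """Softmax left-choice probability from the value difference."""
    z = params.beta_dq * (params.beta0 + q_left - q_right)
    return float(1.0 / (1.0 + np.exp(-z)))


def _rl_loglik_py(c, r, alpha_rew, alpha_unr, delta, beta_dq, beta0):
    qL = 0.0
    qR = 0.0
    ll = 0.0
    lo, hi = PROB_CLIP, 1.0 - PROB_CLIP
    for t in range(c.shape[0]):
        z = beta_dq * (beta0 + qL - qR)
        pL = 1.0 / (1.0 + np.exp(-z))
        p = pL if c[t] == 1 else 1.0 - pL
        if p < lo:
            p = lo
        elif p > hi:
            p = hi
        ll += np.log(p)
        alpha = alpha_rew if r[t] == 1.0 else alpha_unr
        if c[t] == 1:
            qL += alpha * (r[t] - qL)
            qR *= 1.0 - delta
        else:
            qR += alpha * (r[t] - qR)
            qL *= 1.0 - delta
    return ll


try:  # jit the forward recursion; it sits in the innermost loop of fitting
    from numba import njit

    _rl_loglik_core = njit(cache=False)(_rl_loglik_py)
except ImportError:  # pragma: no cover
    _rl_loglik_core = _rl_loglik_py


def _session_arrays(table: SessionTable) -> tuple[np.ndarray, np.ndarray]:
    vt = table.valid_trials()
    c = (table.choice_sign() > 0).astype(np.int64)
    r = vt.reward.astype(np.float64)
    return c, r


def rl_loglik(table: SessionTable, params: RLParams) -> float:
    """Total log-likelihood of the observed choices under the RL model.

    The value recursion is driven by the observed choices and rewards
    (one-step-ahead prediction); Q values start at 0 for both ports.
    """
    c, r = _session_arrays(table)
    if c.size == 0:
        return 0.0
    return float(
        _rl_loglik_core(
            c, r, params.alpha_rew, params.alpha_unr, params.delta,
            params.beta_dq, params.beta0,
        )
    )


def bias_only_loglik(table: SessionTable) -> float:
    """Log-likelihood of the one-parameter constant-bias null at its MLE.

    The null keeps only the softmax bias (a single free scalar on the
    logit), so its MLE is the empirical left-choice rate.
    """
    c, _ = _session_arrays(table)
    n = c.size
    if n == 0:
        return 0.0
    p = np.clip(c.mean(), PROB_CLIP, 1.0 - PROB_CLIP)
    k = c.sum()
    return float(k * np.log(p) + (n - k) * np.log(1.0 - p))


def fit_rl(table: SessionTable, n_starts: int = 10, seed: int = 0) -> RLFit:
    """Bounded maximum-likelihood fit (L-BFGS-B), best of `n_starts` starts."""
    c, r = _session_arrays(table)
    n = c.size
    if n == 0:
        raise ValueError("cannot fit an empty session")
    rng = np.random.default_rng(seed)

    def negloglik(x):
        return -_rl_loglik_core(c, r, x[0], x[1], x[2], x[3], x[4])

    lb = np.array([b[0] for b in RL_BOUNDS])
    ub = np.array([b[1] for b in RL_BOUNDS])
    best = None
    n_ok = 0
    for _ in range(n_starts):
        x0 = rng.uniform(lb, ub)
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=RL_BOUNDS)
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"RL fit failed on all {n_starts} starts")
    params = RLParams.from_array(best.x)
    ll = -float(best.fun)
    index = (ll - bias_only_loglik(table)) / n
    return RLFit(params=params, loglik=ll, rl_index=index, n_trials=n)


def rl_index(table: SessionTable, fit: RLFit) -> float:
    """Per-trial log-likelihood improvement of the RL fit over the bias null."""
    n = table.n_valid
    if n == 0:
        return 0.0
    return (rl_loglik(table, fit.params) - bias_only_loglik(table)) / n
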