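"""Internal logistic-MLE helper.

Binary logistic regression fit by L-BFGS-B with analytic gradients and a
tiny ridge term (default 1e-6) as a numerical guard against perfect
separation.  All choice models in this package that are linear in their
parameters (history GLM, fixed-kernel decay fits, quasi-hyperbolic fits)
go through this one code path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

PROB_CLIP = 1e-10


def bernoulli_loglik(logits: np.ndarray, y: np.ndarray) -> float:
    """Sum of log P(y | logits) for a Bernoulli-logit model, clip-guarded."""
    p = np.clip(expit(logits), PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-6,
    w0: np.ndarray | None = None,
    nonneg: bool = False,
) -> tuple[np.ndarray, float]:
    """Fit y ~ Bernoulli(logistic(X w + b)).

    Returns (weights, intercept).  `ridge` penalizes weights only, not the
    intercept; at 1e-6 it is a separation guard, not a real prior.  With
    `nonneg` the weights (not the intercept) are constrained >= 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    Xa = np.column_stack([X, np.ones(n)])

    def negloglik(w):
        z = Xa @ w
        # log-lik via log_expit for stability: y*log p + (1-y)*log(1-p)
        ll = np.sum(y * log_expit(z) + (1.0 - y) * log_expit(-z))
        pen = 0.5 * ridge * np.dot(w[:k], w[:k])
        p = expit(z)
        grad = -Xa.T @ (y - p)
        grad[:k] += ridge * w[:k]
        return -(ll) + pen, grad

    start = np.zeros(k + 1) if w0 is None else np.asarray(w0, dtype=float)
    bounds = [(0.0, None)] * k + [(None, None)] if nonneg else None
    if nonneg:
        start = np.maximum(start, 0.0)
        start[k] = (w0[k] if w0 is not None else 0.0)
    res = minimize(negloglik, start, jac=True, method="L-BFGS-B", bounds=bounds)
    w = res.x
    return w[:k], float(w[k])


def logistic_loglik(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float) -> float:
    return bernoulli_loglik(np.asarray(X, dtype=float) @ np.asarray(w, dtype=float) + b,
                            np.asarray(y, dtype=float))
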