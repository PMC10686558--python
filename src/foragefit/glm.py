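"""Lagged-history logistic regressions of choice, the inactivation-split
lasso variant, decay-curve fits to mean weights, and win-stay/lose-switch
metrics.

The basic model predicts the left-choice probability from the signed
rewarded-choice and unrewarded-choice history over the past `n_lags`
trials (default 10) plus a bias:

    logit P_L(t) = sum_i b_rewc(i) RewC(t-i) + sum_i b_unrc(i) UnrC(t-i) + b0

The inactivation variant estimates separate 5-lag weight blocks for
control and inactivation trials with an l1 penalty, fit on repeated
matched subsamples of the two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.linear_model import LogisticRegression

from ._logistic import bernoulli_loglik, fit_logistic, logistic_loglik
from .decay import inactivation_condition_masks, kernel
from .session import SessionTable, encode_history

LASSO_GRID = np.logspace(-3, 1, 10)  # l1 penalty (lambda) grid


@dataclass
class GLMWeights:
    beta_rewc: np.ndarray
    beta_unrc: np.ndarray
    beta0: float
    loglik: float = np.nan

    @property
    def n_lags(self) -> int:
        return len(self.beta_rewc)


@dataclass
class InactGLMWeights:
    ctrl: GLMWeights
    inac: GLMWeights
    n_iterations: int
    heldout_loglik: float
    sum_abs_rewc_ctrl: float = field(init=False)
    sum_abs_rewc_inac: float = field(init=False)

    def __post_init__(self):
        self.sum_abs_rewc_ctrl = float(np.abs(self.ctrl.beta_rewc).sum())
        self.sum_abs_rewc_inac = float(np.abs(self.inac.beta_rewc).sum())


@dataclass
class WeightCurveFit:
    family: str
    amplitude: float
    tau: float
    aic: float
    rss: float


def fit_history_glm(table: SessionTable, n_lags: int = 10) -> GLMWeights:
    """Unpenalized ML logistic fit of choice on lagged RewC/UnrC history.

    A 1e-6 ridge inside the solver guards against perfect separation but is
    far below any interpretable prior.
    """
    design = encode_history(table, n_lags)
    X = np.hstack([design.rewc, design.unrc])
    w, b0 = fit_logistic(X, design.y)
    ll = logistic_loglik(X, design.y, w, b0)
    return GLMWeights(
        beta_rewc=w[:n_lags], beta_unrc=w[n_lags:], beta0=b0, loglik=ll
    )


def _inactivation_design(tables: list, n_lags: int):
    """Split-condition design rows pooled over sessions.

    Columns: [rewc*Ctrl (n_lags), unrc*Ctrl (n_lags), Ctrl,
              rewc*Inac (n_lags), unrc*Inac (n_lags), Inac];
    rows are restricted to qualifying trials (inactivation trials, and
    control trials more than 3 trials after an inactivation).
    """
    rows, ys, conds = [], [], []
    for table in tables:
        d = encode_history(table, n_lags)
        ctrl, inac = inactivation_condition_masks(table)
        for flag, mask in ((0, ctrl), (1, inac)):
            h = np.hstack([d.rewc[mask], d.unrc[mask], np.ones((mask.sum(), 1))])
            block = np.zeros((mask.sum(), 2 * (2 * n_lags + 1)))
            off = flag * (2 * n_lags + 1)
            block[:, off : off + 2 * n_lags + 1] = h
            rows.append(block)
            ys.append(d.y[mask])
            conds.append(np.full(mask.sum(), flag))
    return np.vstack(rows), np.concatenate(ys), np.concatenate(conds)


def _lasso_fit(X, y, lam):
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", fit_intercept=False,
        max_iter=500, random_state=0,
    )
    model.fit(X, y)
    return model.coef_[0]


def fit_history_glm_inactivation(
    tables: list,
    n_lags: int = 5,
    n_iterations: int = 1000,
    seed: int = 0,
) -> InactGLMWeights:
    """Condition-split lasso history regression on matched subsamples.

    Each iteration trains on a random 90% of inactivation trials plus an
    equal-count random control subset, with the l1 penalty chosen by
    held-out log-likelihood within the training subsample, and evaluates
    on the remaining matched trials.  Reported weights are means across
    iterations.
    """
    X, y, cond = _inactivation_design(tables, n_lags)
    inac_idx = np.where(cond == 1)[0]
    ctrl_idx = np.where(cond == 0)[0]
    if inac_idx.size < 20:
        raise ValueError(f"only {inac_idx.size} inactivation trials; need >= 20")
    rng = np.random.default_rng(seed)
    n_train_inac = max(int(round(0.9 * inac_idx.size)), 1)
    coefs = np.zeros((n_iterations, X.shape[1]))
    heldout = np.zeros(n_iterations)
    for it in range(n_iterations):
        perm = rng.permutation(inac_idx)
        tr_inac, te_inac = perm[:n_train_inac], perm[n_train_inac:]
        ctrl_perm = rng.permutation(ctrl_idx)
        tr_ctrl = ctrl_perm[: tr_inac.size]
        te_ctrl = ctrl_perm[tr_inac.size : tr_inac.size + te_inac.size]
        tr = np.concatenate([tr_inac, tr_ctrl])
        te = np.concatenate([te_inac, te_ctrl])
        # penalty selection on an internal half-split of the training rows
        half = rng.permutation(tr)
        a, b = half[: half.size // 2], half[half.size // 2 :]
        best_lam, best_ll = None, -np.inf
        for lam in LASSO_GRID:
            w = _lasso_fit(X[a], y[a], lam)
            ll = bernoulli_loglik(X[b] @ w, y[b])
            if ll > best_ll:
                best_ll, best_lam = ll, lam
        w = _lasso_fit(X[tr], y[tr], best_lam)
        coefs[it] = w
        heldout[it] = (
            bernoulli_loglik(X[te] @ w, y[te]) / te.size if te.size else np.nan
        )
    mean = coefs.mean(axis=0)
    k = n_lags
    ctrl_w = GLMWeights(mean[:k], mean[k : 2 * k], float(mean[2 * k]))
    inac_w = GLMWeights(
        mean[2 * k + 1 : 3 * k + 1], mean[3 * k + 1 : 4 * k + 1], float(mean[4 * k + 1])
    )
    return InactGLMWeights(
        ctrl=ctrl_w, inac=inac_w, n_iterations=n_iterations,
        heldout_loglik=float(np.nanmean(heldout)),
    )


def fit_weight_curve(weights, family: str) -> WeightCurveFit:
    """Least-squares decay-curve fit to mean regression weights by lag.

    Fits amplitude * w_i(tau) to the weight-vs-lag curve and scores it with
    the Gaussian-residual AIC, n*ln(RSS/n) + 2k, k = 2.
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    if n < 4:
        raise ValueError("need at least 4 lags for a curve fit")

    def resid(x):
        amp, ltau = x
        return amp * kernel(family, float(np.exp(ltau)), n) - w

    best = None
    for ltau0 in np.log([0.5, 2.0, 8.0]):
        res = least_squares(resid, x0=np.array([w[0], ltau0]),
                            bounds=([-np.inf, np.log(1e-3)], [np.inf, np.log(1e3)]))
        if best is None or res.cost < best.cost:
            best = res
    rss = float(np.sum(resid(best.x) ** 2))
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * 2
    return WeightCurveFit(
        family=family, amplitude=float(best.x[0]), tau=float(np.exp(best.x[1])),
        aic=float(aic), rss=rss,
    )


def win_stay_lose_switch(table: SessionTable) -> tuple[float, float]:
    """Normalized win-stay and lose-switch probabilities.

    Transitions are consecutive valid-trial pairs (pairs separated by an
    invalid trial are skipped).  P(stay|win) is normalized by the overall
    stay probability, the mean of P(stay|win) and P(stay|lose); similarly
    for P(switch|lose).  Undefined conditionals yield NaN, not an error.
    """
    ok = table.valid == 1
    stays_win, stays_lose = [], []
    for t in range(len(table) - 1):
        if not (ok[t] and ok[t + 1]):
            continue
        stay = table.choice[t] == table.choice[t + 1]
        (stays_win if table.reward[t] == 1 else stays_lose).append(stay)
    p_stay_win = np.mean(stays_win) if stays_win else np.nan
    p_stay_lose = np.mean(stays_lose) if stays_lose else np.nan
    denom_stay = np.mean([p_stay_win, p_stay_lose])
    denom_switch = np.mean([1.0 - p_stay_win, 1.0 - p_stay_lose])
    ws = p_stay_win / denom_stay if denom_stay > 0 else np.nan
    ls = (1.0 - p_stay_lose) / denom_switch if denom_switch > 0 else np.nan
    return float(ws), float(ls)
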