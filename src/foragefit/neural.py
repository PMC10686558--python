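"""Per-cell reward-history encoding models and timescale statistics.

Trial-mean (ready-period) activity of each neuron is modeled as a linear
function of the signed rewarded-choice history and the upcoming choice:

    lag-1:  A(t) = b_rewc RewC(t-1)                         + b_c C(t) + b0
    exp:    A(t) = b_rewc sum_i RewC(t-i) e^{(1-i)/tau}     + b_c C(t) + b0
    hyp:    A(t) = b_rewc sum_i RewC(t-i) / (1 + (i-1)/tau) + b_c C(t) + b0

with tau constrained to (0, 100].  Modulation significance uses the
t test on b_rewc in the lag-1 model at alpha = 0.05, with a trial-shuffle
control for the chance rate.  Split-half tau stability and bootstrapped
cross-area median tests quantify the heterogeneity of the recovered
timescales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .decay import contiguous_folds, kernel
from .session import NeuralSession, SessionTable, history_signals, lag_matrix

DEFAULT_N_LAGS = 15
TAU_MAX = 100.0
TAU_MIN = 1e-2
TAU_BOUNDARY = 99.5  # tau-hat above this is flagged boundary-pinned
ALPHA = 0.05


@dataclass
class CellFit:
    beta_rewc: float
    beta_choice: float
    beta0: float
    p_rewc: float
    family: str
    loglik: float
    tau: float = np.nan
    boundary: bool = False
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_rewc) and self.p_rewc < ALPHA)


@dataclass
class TauStats:
    taus_by_area: dict
    medians: dict
    reference: str
    pvals: dict
    qvals: dict = field(default_factory=dict)


def _cell_regressors(table: SessionTable, n_lags: int):
    rewc, _, y = history_signals(table)
    L = lag_matrix(rewc, n_lags)
    c_t = 2.0 * y - 1.0
    return L, c_t


def _gauss_loglik(rss: float, n: int) -> float:
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def fit_cell_lag1(activity: np.ndarray, table: SessionTable) -> CellFit:
    """OLS of activity on RewC(t-1), upcoming choice C(t), and an intercept."""
    a = np.asarray(activity, dtype=float)
    L, c_t = _cell_regressors(table, 1)
    if a.size != c_t.size:
        raise ValueError("activity length must equal the valid-trial count")
    if np.ptp(a) == 0:
        return CellFit(0.0, 0.0, float(a[0]) if a.size else 0.0, np.nan,
                       "lag1", np.nan, degenerate=True)
    X = sm.add_constant(np.column_stack([L[:, 0], c_t]), has_constant="add")
    res = sm.OLS(a, X).fit()
    rss = float(res.ssr)
    return CellFit(
        beta_rewc=float(res.params[1]), beta_choice=float(res.params[2]),
        beta0=float(res.params[0]), p_rewc=float(res.pvalues[1]),
        family="lag1", loglik=_gauss_loglik(rss, a.size),
    )


def _decay_ols(a, L, c_t, family, tau):
    """Inner OLS at fixed tau; returns (rss, coef [hist, choice, const])."""
    h = L @ kernel(family, tau, L.shape[1])
    X = np.column_stack([h, c_t, np.ones_like(a)])
    coef, _, _, _ = np.linalg.lstsq(X, a, rcond=None)
    rss = float(np.sum((a - X @ coef) ** 2))
    return rss, coef, X


def fit_cell_decay(
    activity: np.ndarray,
    table: SessionTable,
    family: str = "exp",
    n_lags: int = DEFAULT_N_LAGS,
) -> CellFit:
    """Nonlinear least squares over (b_rewc, tau, b_c, b0), tau in (0, 100].

    tau is profiled out: at fixed tau the model is linear, so the search is
    a 1-d bounded minimization of the profile RSS over log tau, started
    from a coarse grid.  The p-value for b_rewc is the t test from the OLS
    at the selected tau.
    """
    a = np.asarray(activity, dtype=float)
    L, c_t = _cell_regressors(table, n_lags)
    if a.size != c_t.size:
        raise ValueError("activity length must equal the valid-trial count")
    if np.ptp(a) == 0:
        return CellFit(0.0, 0.0, float(a[0]), np.nan, family, np.nan,
                       degenerate=True)

    def profile_rss(ltau):
        return _decay_ols(a, L, c_t, family, float(np.exp(ltau)))[0]

    lo, hi = np.log(TAU_MIN), np.log(TAU_MAX)
    grid = np.linspace(lo, hi, 25)
    rss_grid = [profile_rss(g) for g in grid]
    k = int(np.argmin(rss_grid))
    a_lo, a_hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(profile_rss, bounds=(a_lo, a_hi), method="bounded")
    ltau = res.x if res.fun <= rss_grid[k] else grid[k]
    tau = float(np.exp(ltau))
    rss, coef, X = _decay_ols(a, L, c_t, family, tau)
    # t test on the history coefficient at the profiled tau
    dof = a.size - X.shape[1]
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(max(rss / dof, 1e-300) * XtX_inv[0, 0])
    tval = coef[0] / se if se > 0 else np.nan
    p = 2.0 * t_dist.sf(abs(tval), dof) if np.isfinite(tval) else np.nan
    return CellFit(
        beta_rewc=float(coef[0]), beta_choice=float(coef[1]), beta0=float(coef[2]),
        p_rewc=float(p), family=family, loglik=_gauss_loglik(rss, a.size),
        tau=tau, boundary=bool(tau >= TAU_BOUNDARY),
    )


def _profile_tau_rows(a, L, c_t, rows, family):
    """Profile-RSS tau search restricted to the given design rows."""

    def rss_at(ltau):
        h = L @ kernel(family, float(np.exp(ltau)), L.shape[1])
        X = np.column_stack([h[rows], c_t[rows], np.ones(rows.size)])
        coef, _, _, _ = np.linalg.lstsq(X, a[rows], rcond=None)
        return float(np.sum((a[rows] - X @ coef) ** 2)), coef

    lo, hi = np.log(TAU_MIN), np.log(TAU_MAX)
    grid = np.linspace(lo, hi, 25)
    rss_grid = [rss_at(g)[0] for g in grid]
    k = int(np.argmin(rss_grid))
    res = minimize_scalar(
        lambda lt: rss_at(lt)[0],
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]),
        method="bounded",
    )
    ltau = res.x if res.fun <= rss_grid[k] else grid[k]
    rss, coef = rss_at(ltau)
    return float(np.exp(ltau)), coef, rss


def cv_compare_cell(
    activity: np.ndarray,
    table: SessionTable,
    n_folds: int = 10,
    seed: int = 0,
    n_lags: int = DEFAULT_N_LAGS,
):
    """Per-cell exp-vs-hyp comparison by held-out Gaussian log-likelihood.

    History predictors are built once from the full session; both decay
    models are fit on the training-fold rows, and held-out trials are
    scored under a Gaussian with the training-fold residual variance.
    Returns a ModelComparison with diff = (hyp - exp) per trial.
    """
    from .decay import ModelComparison

    a = np.asarray(activity, dtype=float)
    L, c_t = _cell_regressors(table, n_lags)
    folds = contiguous_folds(a.size, n_folds)
    per_fold = []
    for test in folds:
        train = np.setdiff1d(np.arange(a.size), test)
        lls = {}
        for fam in ("exp", "hyp"):
            tau, coef, rss = _profile_tau_rows(a, L, c_t, train, fam)
            h = L @ kernel(fam, tau, n_lags)
            pred = coef[0] * h + coef[1] * c_t + coef[2]
            s2 = max(rss / train.size, 1e-300)
            resid = a[test] - pred[test]
            lls[fam] = float(
                np.mean(-0.5 * (np.log(2 * np.pi * s2) + resid**2 / s2))
            )
        per_fold.append((lls["exp"], lls["hyp"]))
    diff = float(np.mean([h - e for e, h in per_fold]))
    return ModelComparison(per_fold=per_fold, diff=diff)


def _subset_table(table: SessionTable, rows: np.ndarray) -> SessionTable:
    """Valid-trial row subset as a SessionTable (history re-derived on subset)."""
    vt = table.valid_trials()
    mask = np.zeros(len(vt), dtype=bool)
    mask[rows] = True
    return vt.subset(mask)


def _lag1_significant_matrix(activity: np.ndarray, table: SessionTable) -> np.ndarray:
    """Vectorized lag-1 significance flags for a cells x trials matrix."""
    A = np.atleast_2d(np.asarray(activity, dtype=float))
    L, c_t = _cell_regressors(table, 1)
    X = np.column_stack([L[:, 0], c_t, np.ones_like(c_t)])
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    coef = pinv @ A.T  # (3, cells)
    resid = A.T - X @ coef
    rss = np.sum(resid**2, axis=0)
    dof = n - k
    XtX_inv00 = np.linalg.pinv(X.T @ X)[0, 0]
    se = np.sqrt(np.maximum(rss / dof, 1e-300) * XtX_inv00)
    tval = np.divide(coef[0], se, out=np.zeros_like(se), where=se > 0)
    p = 2.0 * t_dist.sf(np.abs(tval), dof)
    return p < ALPHA


def significant_fraction(population: NeuralSession, table: SessionTable) -> float:
    """Fraction of cells with significant lag-1 history modulation."""
    return float(_lag1_significant_matrix(population.activity, table).mean())


def shuffle_control(
    population: NeuralSession,
    table: SessionTable,
    n_shuffles: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Chance significant-fraction distribution from trial-shuffled activity.

    Each shuffle permutes every cell's activity independently across trials
    and refits the lag-1 model; returns the significant fraction per
    shuffle.
    """
    rng = np.random.default_rng(seed)
    A = population.activity
    n_cells, n_trials = A.shape
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = np.argsort(rng.random((n_cells, n_trials)), axis=1)
        shuffled = np.take_along_axis(A, perm, axis=1)
        out[s] = _lag1_significant_matrix(shuffled, table).mean()
    return out


def split_half_taus(
    activity: np.ndarray,
    table: SessionTable,
    n_lags: int = DEFAULT_N_LAGS,
    min_half: int = 50,
) -> tuple[float, float, bool]:
    """Independent exponential-model taus from the two halves of a session.

    The session's valid trials are split at the midpoint; the exponential
    cell model is fit independently per half (history predictors are built
    within each half), with no cross-half constraint.  The cell is eligible
    for timescale analyses only if b_rewc is significant (p < 0.05) in
    BOTH halves.
    """
    a = np.asarray(activity, dtype=float)
    n = a.size
    half = n // 2
    if half < min_half:
        raise ValueError(f"half-session of {half} trials is below {min_half}")
    idx1, idx2 = np.arange(half), np.arange(half, n)
    fits = [
        fit_cell_decay(a[idx], _subset_table(table, idx), "exp", n_lags)
        for idx in (idx1, idx2)
    ]
    eligible = all(f.significant for f in fits)
    return fits[0].tau, fits[1].tau, eligible


def tau_distribution_test(
    taus: pd.DataFrame,
    reference: str = "RSC",
    n_boot: int = 100_000,
    seed: int = 0,
) -> TauStats:
    """Bootstrapped cross-area test of tau medians against a reference area.

    `taus` needs columns [tau, area, animal].  Per bootstrap, an equal
    number of samples is drawn (with replacement) from each area, split
    evenly across that area's animals; each non-reference area's median
    difference from the reference yields a two-sided bootstrap p-value,
    Benjamini-Hochberg corrected across areas.
    """
    rng = np.random.default_rng(seed)
    areas = list(dict.fromkeys(taus["area"]))
    if reference not in areas:
        raise ValueError(f"reference area {reference!r} not present")
    if len(areas) < 2:
        raise ValueError("need at least two areas")
    groups = {
        ar: [g["tau"].to_numpy(float) for _, g in taus[taus["area"] == ar].groupby("animal")]
        for ar in areas
    }
    n_draw = min(len(taus[taus["area"] == ar]) for ar in areas)
    boot_medians = {}
    for ar in areas:
        animals = groups[ar]
        per = max(n_draw // len(animals), 1)
        cols = [
            arr[rng.integers(0, arr.size, size=(n_boot, per))] for arr in animals
        ]
        boot_medians[ar] = np.median(np.concatenate(cols, axis=1), axis=1)
    medians = {ar: float(np.median(np.concatenate(groups[ar]))) for ar in areas}
    pvals = {}
    for ar in areas:
        if ar == reference:
            continue
        d = boot_medians[ar] - boot_medians[reference]
        p_lo = (np.sum(d <= 0) + 1) / (n_boot + 1)
        p_hi = (np.sum(d >= 0) + 1) / (n_boot + 1)
        pvals[ar] = float(min(1.0, 2.0 * min(p_lo, p_hi)))
    keys = list(pvals)
    if keys:
        _, q, _, _ = multipletests([pvals[k] for k in keys], method="fdr_bh")
        qvals = {k: float(v) for k, v in zip(keys, q)}
    else:
        qvals = {}
    return TauStats(
        taus_by_area={ar: np.concatenate(groups[ar]) for ar in areas},
        medians=medians, reference=reference, pvals=pvals, qvals=qvals,
    )
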