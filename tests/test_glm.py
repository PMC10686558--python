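"""History GLM, inactivation-split lasso, weight-curve fits, win-stay metrics."""

import numpy as np
import pytest

import foragefit as ff
from foragefit._logistic import logistic_loglik
from foragefit.decay import inactivation_condition_masks
from foragefit.session import encode_history


def test_glm_recovers_exponential_decay(exp_session):
    w = ff.fit_history_glm(exp_session, n_lags=10)
    # generating kernel: 2 * e^{(1-i)/1.5}; early lags positive and decaying
    assert w.beta_rewc[0] > w.beta_rewc[2] > w.beta_rewc[5]
    assert w.beta_rewc[0] > 1.0
    assert np.all(np.abs(w.beta_unrc) < 0.5)


def test_glm_null_calibration(coin_session):
    w = ff.fit_history_glm(coin_session, n_lags=10)
    # rough 95% CI half-width for a logistic coefficient with +-1 regressors
    n = coin_session.n_valid
    half_width = 1.96 * 2.0 / np.sqrt(n)
    assert np.all(np.abs(w.beta_rewc) < 3 * half_width)
    assert np.all(np.abs(w.beta_unrc) < 3 * half_width)


def test_glm_label_flip_negates_weights(exp_session):
    flipped = {"L": "R", "R": "L"}
    mirror = ff.SessionTable(
        choice=np.array([flipped[c] for c in exp_session.choice], dtype=object),
        reward=exp_session.reward, block=exp_session.block,
        inactivation=exp_session.inactivation, valid=exp_session.valid,
    )
    a = ff.fit_history_glm(exp_session, n_lags=5)
    b = ff.fit_history_glm(mirror, n_lags=5)
    # regressors and response flip together, so the weights are invariant
    # and only the side bias changes sign
    assert np.allclose(a.beta_rewc, b.beta_rewc, atol=1e-4)
    assert np.allclose(a.beta_unrc, b.beta_unrc, atol=1e-4)
    assert np.isclose(a.beta0, -b.beta0, atol=1e-4)


def test_glm_loglik_beats_zero_weights(exp_session):
    w = ff.fit_history_glm(exp_session, n_lags=10)
    d = encode_history(exp_session, 10)
    X = np.hstack([d.rewc, d.unrc])
    ll_zero = logistic_loglik(X, d.y, np.zeros(20), 0.0)
    assert w.loglik >= ll_zero


@pytest.fixture(scope="module")
def inactivation_tables():
    agent = ff.hyp_agent(2.0, 2.0, inact_gain_scale=0.3)
    tables = []
    for s in (21, 22):
        env = ff.make_environment(ff.TaskConfig(n_trials=2000, seed=s))
        tables.append(
            ff.simulate_agent(agent, env, 2000, seed=s, inactivation_frac=0.15)
        )
    return tables


def test_condition_masks_exclude_post_inactivation_window(tiny_session):
    ctrl, inac = inactivation_condition_masks(tiny_session, window=3)
    # valid trials: idx 0,1,2 ctrl; idx 3 inactivation; idx 4 within window
    assert inac.tolist() == [False, False, False, True, False]
    assert ctrl.tolist() == [True, True, True, False, False]


def test_inactivation_glm_detects_reduced_history_gain(inactivation_tables):
    res = ff.fit_history_glm_inactivation(
        inactivation_tables, n_iterations=40, seed=0
    )
    assert res.sum_abs_rewc_inac < res.sum_abs_rewc_ctrl
    assert res.ctrl.n_lags == res.inac.n_lags == 5


def test_inactivation_glm_null_effect():
    agent = ff.hyp_agent(2.0, 2.0)  # identical policy on flagged trials
    env = ff.make_environment(ff.TaskConfig(n_trials=3000, seed=31))
    tab = ff.simulate_agent(agent, env, 3000, seed=31, inactivation_frac=0.15)
    res = ff.fit_history_glm_inactivation([tab], n_iterations=40, seed=0)
    # with ~450 flagged trials the sum-of-weights summary is the stable one
    assert abs(res.sum_abs_rewc_ctrl - res.sum_abs_rewc_inac) < 1.5
    assert res.ctrl.beta_rewc[0] > 0 and res.inac.beta_rewc[0] > 0


def test_inactivation_glm_deterministic(inactivation_tables):
    a = ff.fit_history_glm_inactivation(inactivation_tables, n_iterations=5, seed=3)
    b = ff.fit_history_glm_inactivation(inactivation_tables, n_iterations=5, seed=3)
    assert np.allclose(a.ctrl.beta_rewc, b.ctrl.beta_rewc)
    assert np.allclose(a.inac.beta_rewc, b.inac.beta_rewc)


def test_inactivation_glm_insufficient_trials():
    n = 40
    rng = np.random.default_rng(0)
    inact = np.zeros(n, dtype=int)
    inact[[10, 25]] = 1  # only 2 inactivation trials
    tab = ff.SessionTable(
        choice=np.array(rng.choice(["L", "R"], n), dtype=object),
        reward=rng.integers(0, 2, n), block=np.zeros(n, dtype=int),
        inactivation=inact, valid=np.ones(n, dtype=int),
    )
    with pytest.raises(ValueError, match="inactivation trials"):
        ff.fit_history_glm_inactivation([tab], n_iterations=2, seed=0)


def test_weight_curve_identifies_generating_family():
    lags = np.arange(1, 11)
    exp_w = 2.0 * np.exp((1 - lags) / 2.5)
    hyp_w = 2.0 / (1 + (lags - 1) / 2.5)
    fe = ff.fit_weight_curve(exp_w, "exp")
    fh = ff.fit_weight_curve(exp_w, "hyp")
    assert fe.aic < fh.aic
    assert np.isclose(fe.tau, 2.5, rtol=1e-3)
    fe2 = ff.fit_weight_curve(hyp_w, "exp")
    fh2 = ff.fit_weight_curve(hyp_w, "hyp")
    assert fh2.aic < fe2.aic


def test_weight_curve_power_monotone_in_snr():
    rng = np.random.default_rng(0)
    lags = np.arange(1, 11)
    truth = 1.5 * np.exp((1 - lags) / 3.0)
    correct = []
    for noise in (0.01, 0.5):
        hits = 0
        for _ in range(40):
            w = truth + rng.normal(0, noise, lags.size)
            hits += ff.fit_weight_curve(w, "exp").aic < ff.fit_weight_curve(w, "hyp").aic
        correct.append(hits / 40)
    assert correct[0] >= 0.95
    assert correct[0] >= correct[1]


def test_weight_curve_needs_four_lags():
    with pytest.raises(ValueError):
        ff.fit_weight_curve([1.0, 0.5, 0.2], "exp")


def make_table(choices, rewards):
    n = len(choices)
    return ff.SessionTable(
        choice=np.array(list(choices), dtype=object), reward=list(rewards),
        block=[0] * n, inactivation=[0] * n, valid=[1] * n,
    )


def test_win_stay_always_stay_agent():
    tab = make_table("LLLLLLLL", [1, 0, 1, 1, 0, 1, 0, 1])
    ws, ls = ff.win_stay_lose_switch(tab)
    assert np.isclose(ws, 1.0)  # stays after wins and losses alike
    assert np.isnan(ls)  # never switches: P(switch|·) = 0/0 normalization


def test_win_stay_strict_wsls_agent():
    # strict win-stay / lose-switch choice sequence
    rewards = [1, 1, 0, 1, 0, 0, 1, 1, 0, 1]
    choices = ["L"]
    for r, c in zip(rewards[:-1], choices):
        choices.append(c if r == 1 else ("R" if c == "L" else "L"))
    tab = make_table(choices, rewards)
    ws, ls = ff.win_stay_lose_switch(tab)
    assert np.isclose(ws, 2.0) and np.isclose(ls, 2.0)


def test_win_stay_random_chooser_near_one(coin_session):
    ws, ls = ff.win_stay_lose_switch(coin_session)
    assert abs(ws - 1.0) < 0.15 and abs(ls - 1.0) < 0.15


def test_win_stay_undefined_without_losses():
    tab = make_table("LRLR", [1, 1, 1, 1])
    ws, ls = ff.win_stay_lose_switch(tab)
    assert np.isnan(ws) and np.isnan(ls)


def test_win_stay_skips_pairs_split_by_invalid_trial():
    tab = ff.SessionTable(
        choice=np.array(["L", "", "R", "R", "R"], dtype=object),
        reward=[1, 0, 1, 0, 0], block=[0] * 5, inactivation=[0] * 5,
        valid=[1, 0, 1, 1, 1],
    )
    ws, ls = ff.win_stay_lose_switch(tab)
    # counted pairs: (2,3) win-stay and (3,4) lose-stay; the L->R transition
    # around the invalid trial must be skipped (it would drag ws below 1)
    assert np.isclose(ws, 1.0)
    assert np.isnan(ls)  # agent never switches
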