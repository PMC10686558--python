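import numpy as np
import pytest

import foragefit as ff


def make_session(agent, n_trials=1000, env_seed=1, sim_seed=2, **sim_kw):
    env = ff.make_environment(ff.TaskConfig(n_trials=n_trials, seed=env_seed))
    return ff.simulate_agent(agent, env, n_trials, seed=sim_seed, **sim_kw)


@pytest.fixture(scope="session")
def hyp_session():
    """1000-trial session from a hyperbolic-kernel agent (beta=2, tau=2)."""
    return make_session(ff.hyp_agent(beta=2.0, tau=2.0))


@pytest.fixture(scope="session")
def exp_session():
    """1000-trial session from an exponential-kernel agent (beta=2, tau=1.5)."""
    return make_session(ff.exp_agent(beta=2.0, tau=1.5), sim_seed=3)


@pytest.fixture(scope="session")
def rl_session():
    """1000-trial session from the RL agent at the reference parameters."""
    params = ff.RLParams(alpha_rew=0.6, alpha_unr=0.3, delta=0.2,
                         beta_dq=3.0, beta0=0.0)
    return make_session(ff.rl_agent(params), sim_seed=4)


@pytest.fixture(scope="session")
def coin_session():
    """History-free Bernoulli(0.5) chooser."""

    class Coin(ff.synth.Agent):
        def reset(self):
            pass

        def choose(self, inactivated=False):
            return 0.5

        def update(self, choice_sign, reward):
            pass

    return make_session(Coin(), sim_seed=5)


@pytest.fixture(scope="session")
def tiny_session():
    """Hand-built 6-trial session with one invalid trial."""
    return ff.SessionTable(
        choice=np.array(["L", "R", "L", "", "R", "L"], dtype=object),
        reward=[1, 0, 0, 0, 1, 1],
        block=[0, 0, 0, 0, 0, 0],
        inactivation=[0, 0, 0, 0, 1, 0],
        valid=[1, 1, 1, 0, 1, 1],
    )


@pytest.fixture(scope="session")
def neural_population(hyp_session):
    """100 synthetic cells, tau log-uniform [0.5, 10], on a 600-trial session."""
    table = make_session(ff.hyp_agent(beta=2.0, tau=2.0), n_trials=600, sim_seed=7)
    rng = np.random.default_rng(11)
    cells = ff.draw_cell_population(100, rng, tau_range=(0.5, 10.0),
                                   beta_rewc=1.0, noise_sd=1.0)
    pop = ff.synth_neural_session(table, cells, seed=13)
    return table, cells, pop
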