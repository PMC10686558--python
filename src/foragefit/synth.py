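"""Synthetic study inputs: the baited foraging task, behavioral agents,
and noisy exponential-integrator neural populations.

The task is a dynamic two-port foraging environment.  On every trial each
port independently receives a bait with its current assignment probability;
once baited, the reward stays at that port until it is chosen.  Assignment
probabilities come in (high, low) pairs — [60%, 10%] or [52.5%, 17.5%] —
that invert every 60–80 trials following the deterministic cycle
[60,10], [10,60], [52.5,17.5], [17.5,52.5], ..., with the first block's
high side chosen at random.

Agents are policy objects that expose P(left) on each trial given their own
choice/outcome history: the Rescorla-Wagner agent (value recursion) and
kernel agents whose logit is a decaying weighted sum of past rewarded
choices — exponential, hyperbolic, or quasi-hyperbolic (a weighted sum of
exponentials).

Synthetic neurons are generated as noisy exponential integrators of the
rewarded-choice history with per-cell time constants, plus an
upcoming-choice term, matching the form of the cell encoding model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rl import RLParams, q_update, rl_choice_prob
from .session import NeuralSession, SessionTable, history_signals, lag_matrix

DEFAULT_PROB_PAIRS = [(0.6, 0.1), (0.525, 0.175)]
DEFAULT_N_LAGS = 15


@dataclass
class TaskConfig:
    n_trials: int = 1000
    prob_pairs: list = field(default_factory=lambda: [p for p in DEFAULT_PROB_PAIRS])
    block_length_range: tuple = (60, 80)
    seed: int = 0

    def __post_init__(self):
        for hi, lo in self.prob_pairs:
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.block_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid block length range")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")


class ForagingEnvironment:
    """Stateful baited two-port environment.  Ports are indexed L=0, R=1."""

    def __init__(self, config: TaskConfig):
        self.config = config
        self.reset(np.random.default_rng(config.seed))

    def _block_cycle(self, flip: bool) -> list:
        cycle = []
        for hi, lo in self.config.prob_pairs:
            cycle.append((hi, lo))
            cycle.append((lo, hi))
        if flip:
            cycle = [(b, a) for a, b in cycle]
        return cycle

    def reset(self, rng: np.random.Generator | None = None):
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        self._cycle = self._block_cycle(flip=bool(self.rng.integers(2)))
        self.baited = np.zeros(2, dtype=bool)
        self.block_index = -1
        self.trials_left_in_block = 0
        self._advance_block()

    def _advance_block(self):
        self.block_index += 1
        lo, hi = self.config.block_length_range
        self.trials_left_in_block = int(self.rng.integers(lo, hi + 1))
        self.probs = self._cycle[self.block_index % len(self._cycle)]

    @property
    def high_side(self) -> str:
        return "L" if self.probs[0] >= self.probs[1] else "R"

    def assign_baits(self):
        """Independent Bernoulli assignment per port; bait persists until chosen."""
        draw = self.rng.random(2) < np.asarray(self.probs)
        self.baited |= draw

    def step(self, choice: str) -> int:
        """Run one trial given the agent's choice; returns the reward (0/1)."""
        self.assign_baits()
        port = 0 if choice == "L" else 1
        reward = int(self.baited[port])
        self.baited[port] = False  # choosing consumes the bait
        self.trials_left_in_block -= 1
        block = self.block_index
        if self.trials_left_in_block == 0:
            self._advance_block()
        self._last_block = block
        return reward


def make_environment(config: TaskConfig) -> ForagingEnvironment:
    return ForagingEnvironment(config)


class Agent:
    """Policy interface: P(left) from own history, with outcome feedback."""

    def reset(self):  # pragma: no cover - overridden
        pass

    def choose(self, inactivated: bool = False) -> float:
        raise NotImplementedError

    def update(self, choice_sign: int, reward: int):
        raise NotImplementedError


class RLAgent(Agent):
    def __init__(self, params: RLParams):
        self.params = params
        self.reset()

    def reset(self):
        self.q = np.zeros(2)  # [left, right]

    def choose(self, inactivated: bool = False) -> float:
        return rl_choice_prob(self.q[0], self.q[1], self.params)

    def update(self, choice_sign: int, reward: int):
        ch = 0 if choice_sign > 0 else 1
        un = 1 - ch
        self.q[ch], self.q[un] = q_update(self.q[ch], self.q[un], reward, self.params)


def _kernel_weights(family: str, tau: float, n_lags: int) -> np.ndarray:
    i = np.arange(1, n_lags + 1, dtype=float)
    if family == "exp":
        return np.exp((1.0 - i) / tau)
    if family == "hyp":
        return 1.0 / (1.0 + (i - 1.0) / tau)
    raise ValueError(f"unknown kernel family {family!r}")


class KernelAgent(Agent):
    """Choice logit = beta * sum_i RewC(t-i) w_i + beta0, w from a decay kernel.

    Optional inactivation parameters replace (beta, kernel) on trials where
    ``choose`` is called with ``inactivated=True`` — used to plant
    history-dependence deficits in simulated inactivation studies.
    """

    def __init__(self, family: str, beta: float, tau: float, beta0: float = 0.0,
                 n_lags: int = DEFAULT_N_LAGS, inact_gain_scale: float = 1.0,
                 inact_tau: float | None = None, inact_family: str | None = None):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        self.beta = beta
        self.beta0 = beta0
        self.n_lags = n_lags
        self.weights = _kernel_weights(family, tau, n_lags)
        ifam = inact_family or family
        itau = inact_tau if inact_tau is not None else tau
        self.inact_weights = inact_gain_scale * _kernel_weights(ifam, itau, n_lags)
        self.reset()

    def reset(self):
        self.rewc = np.zeros(self.n_lags)  # rewc[i-1] = RewC(t-i)

    def choose(self, inactivated: bool = False) -> float:
        w = self.inact_weights if inactivated else self.weights
        z = self.beta * float(self.rewc @ w) + self.beta0
        return float(1.0 / (1.0 + np.exp(-z)))

    def update(self, choice_sign: int, reward: int):
        self.rewc = np.roll(self.rewc, 1)
        self.rewc[0] = choice_sign * reward


class QuasiHypAgent(Agent):
    """Logit = sum_m beta_m * (exp-kernel_m convolved RewC) + beta0."""

    def __init__(self, betas, taus, beta0: float = 0.0, n_lags: int = DEFAULT_N_LAGS):
        betas = np.asarray(betas, dtype=float)
        taus = np.asarray(taus, dtype=float)
        if betas.shape != taus.shape or betas.ndim != 1:
            raise ValueError("betas and taus must be 1-d arrays of equal length")
        if np.any(taus <= 0):
            raise ValueError("all taus must be > 0")
        self.n_lags = n_lags
        self.net_weights = sum(
            b * _kernel_weights("exp", t, n_lags) for b, t in zip(betas, taus)
        )
        self.beta0 = beta0
        self.reset()

    def reset(self):
        self.rewc = np.zeros(self.n_lags)

    def choose(self, inactivated: bool = False) -> float:
        z = float(self.rewc @ self.net_weights) + self.beta0
        return float(1.0 / (1.0 + np.exp(-z)))

    def update(self, choice_sign: int, reward: int):
        self.rewc = np.roll(self.rewc, 1)
        self.rewc[0] = choice_sign * reward


def rl_agent(params: RLParams) -> RLAgent:
    return RLAgent(params)


def exp_agent(beta: float, tau: float, beta0: float = 0.0,
              n_lags: int = DEFAULT_N_LAGS, **kw) -> KernelAgent:
    return KernelAgent("exp", beta, tau, beta0, n_lags, **kw)


def hyp_agent(beta: float, tau: float, beta0: float = 0.0,
              n_lags: int = DEFAULT_N_LAGS, **kw) -> KernelAgent:
    return KernelAgent("hyp", beta, tau, beta0, n_lags, **kw)


def quasi_hyp_agent(betas, taus, beta0: float = 0.0,
                    n_lags: int = DEFAULT_N_LAGS) -> QuasiHypAgent:
    return QuasiHypAgent(betas, taus, beta0, n_lags)


def simulate_agent(
    agent: Agent,
    env: ForagingEnvironment,
    n_trials: int,
    seed: int,
    inactivation_frac: float = 0.0,
    inactivation_min_gap: int = 3,
) -> SessionTable:
    """Run an agent in the environment for `n_trials` valid trials.

    If ``inactivation_frac`` > 0, trials are flagged for inactivation at that
    rate, constrained to fall at least ``inactivation_min_gap`` trials after
    the previous inactivation; the flag is passed to the agent's policy.
    """
    rng = np.random.default_rng(seed)
    env.reset(rng)
    agent.reset()
    choice = np.empty(n_trials, dtype=object)
    reward = np.zeros(n_trials, dtype=int)
    block = np.zeros(n_trials, dtype=int)
    inact = np.zeros(n_trials, dtype=int)
    since_inact = inactivation_min_gap + 1
    for t in range(n_trials):
        if inactivation_frac > 0 and since_inact > inactivation_min_gap:
            if rng.random() < inactivation_frac:
                inact[t] = 1
        since_inact = 0 if inact[t] else since_inact + 1
        p_left = agent.choose(inactivated=bool(inact[t]))
        if not 0.0 <= p_left <= 1.0:
            raise ValueError(f"agent returned P(left)={p_left} outside [0, 1]")
        c = "L" if rng.random() < p_left else "R"
        r = env.step(c)
        choice[t] = c
        reward[t] = r
        block[t] = env._last_block
        agent.update(1 if c == "L" else -1, r)
    return SessionTable(
        choice=choice,
        reward=reward,
        block=block,
        inactivation=inact,
        valid=np.ones(n_trials, dtype=int),
    )


@dataclass
class CellGenParams:
    """Generative parameters for one synthetic neuron."""

    tau: float
    beta_rewc: float = 1.0
    beta_choice: float = 0.0
    beta0: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_neural_session(
    table: SessionTable,
    cells: list[CellGenParams],
    seed: int,
    n_lags: int = DEFAULT_N_LAGS,
    area: str = "",
    session_id: str = "",
) -> NeuralSession:
    """Generate a cells x trials activity matrix from a behavioral session.

    Each cell integrates the signed rewarded-choice history with an
    exponential kernel of its own time constant, adds an upcoming-choice
    term, Gaussian trial noise, and is z-scored across trials.
    """
    if not cells:
        raise ValueError("cell list is empty")
    rng = np.random.default_rng(seed)
    rewc, _, y = history_signals(table)
    L = lag_matrix(rewc, n_lags)
    c_t = 2.0 * y - 1.0  # upcoming choice, +1 left / -1 right
    n = len(y)
    activity = np.empty((len(cells), n))
    for j, cell in enumerate(cells):
        drive = (
            cell.beta_rewc * (L @ _kernel_weights("exp", cell.tau, n_lags))
            + cell.beta_choice * c_t
            + cell.beta0
        )
        a = drive + rng.normal(0.0, cell.noise_sd, size=n)
        sd = a.std()
        activity[j] = (a - a.mean()) / sd if sd > 0 else a - a.mean()
    return NeuralSession(activity=activity, area=area, session_id=session_id)


def draw_cell_population(
    n_cells: int,
    rng: np.random.Generator,
    tau_range: tuple = (0.5, 10.0),
    beta_rewc: float = 1.0,
    beta_choice: float = 0.0,
    noise_sd: float = 1.0,
) -> list[CellGenParams]:
    """Heterogeneous population with log-uniform time constants."""
    taus = np.exp(rng.uniform(np.log(tau_range[0]), np.log(tau_range[1]), n_cells))
    return [
        CellGenParams(tau=float(t), beta_rewc=beta_rewc, beta_choice=beta_choice,
                      noise_sd=noise_sd)
        for t in taus
    ]
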