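"""Seedable simulators of the four operant procedures.

Each engine is a pure function of (agent, config, seed) and returns a
long-format pandas trial log (schema in :mod:`ratrisk.io`).

Risky decision-making task (RDT): five blocks of 8 forced- then 10
free-choice trials; a small-lever press earns 1 pellet, a large-lever press
earns 2 pellets plus a footshock whose probability is 0/25/50/75/100% by
block.  On the four forced large-lever trials of a block the shock outcomes
are *dependent*: exactly round(4p) of them carry a shock (e.g. one and only
one in the 25% block), at seeded positions.  Free-choice shock outcomes are
independent Bernoulli(p) draws consumed only on large-lever presses.  The
large reward is always delivered on a large press, shock or not.

Probabilistic reversal learning (PRL): 200 trials; the randomly chosen
"correct" lever rewards at 0.80 and the other at 0.20; eight consecutive
correct choices swap the lever identities.  An omission resets the
consecutive-correct counter (the counter-reset behavior of omissions is an
implementation choice; see docs).

Progressive ratio (PR): the r-th reward requires N = r(r+1)(r+2)/6 presses
(1, 4, 10, 20, 35, ...); the session ends when 10 min pass without a reward.
Breakpoint is the press requirement of the last completed ratio.

Shock-reactivity staircase: amplitude starts at 50 uA and moves up 25 uA
after each non-flinch, down 25 uA after each flinch, never below the start
amplitude, until at least three flinches have occurred and the last delivery
did not flinch; the threshold is the mean of the first three flinch
amplitudes.  An observer that flinches even at the floor terminates there
with the floor as its threshold (documented boundary case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import AgentSpec, PRPersistence
from .rl import RLParams, choice_probabilities, initial_values, update_value

# ---------------------------------------------------------------------------
# configs


class ConfigError(ValueError):
    """A task configuration that cannot be realized."""


@dataclass(frozen=True)
class RDTConfig:
    n_blocks: int = 5
    forced_per_block: int = 8  # 4 per lever
    free_per_block: int = 10
    shock_probs: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75, 1.0)
    large_reward: int = 2
    small_reward: int = 1
    nosepoke_window_s: float = 10.0

    def __post_init__(self) -> None:
        if len(self.shock_probs) != self.n_blocks:
            raise ConfigError("shock_probs length must equal n_blocks")
        if any(not 0.0 <= p <= 1.0 for p in self.shock_probs):
            raise ConfigError("shock probabilities must be in [0, 1]")
        if self.forced_per_block % 2 != 0:
            raise ConfigError("forced_per_block must be even (half per lever)")
        if self.free_per_block < 0 or self.forced_per_block < 0:
            raise ConfigError("trial counts must be >= 0")


@dataclass(frozen=True)
class PRLConfig:
    n_trials: int = 200
    p_reward_correct: float = 0.80
    p_reward_incorrect: float = 0.20
    reversal_criterion: int = 8
    response_window_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_reward_incorrect < self.p_reward_correct <= 1.0:
            raise ConfigError("need 0 <= p_incorrect < p_correct <= 1")
        if self.reversal_criterion < 1:
            raise ConfigError("reversal_criterion must be >= 1")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")


@dataclass(frozen=True)
class PRConfig:
    session_cap_min: float = 120.0
    giving_up_window_min: float = 10.0

    def __post_init__(self) -> None:
        if self.giving_up_window_min <= 0:
            raise ConfigError("giving_up_window_min must be > 0")
        if self.session_cap_min <= 0:
            raise ConfigError("session_cap_min must be > 0")


@dataclass(frozen=True)
class StaircaseConfig:
    preexposure_amp: float = 400.0
    start_amp: float = 50.0
    step: float = 25.0
    min_flinches: int = 3
    pulse_s: float = 0.5
    max_amp: float = 2000.0  # safety cap: observers silent up to here abort

    def __post_init__(self) -> None:
        if self.step <= 0 or self.start_amp <= 0:
            raise ConfigError("step and start_amp must be > 0")
        if self.min_flinches < 1:
            raise ConfigError("min_flinches must be >= 1")
        if self.max_amp <= self.start_amp:
            raise ConfigError("max_amp must exceed start_amp")


# ---------------------------------------------------------------------------
# risky decision-making task

# latency model (fabricated; documented in docs/methods.md): lognormal with
# sigma 0.35, median 1 s on the small lever and rising with the block's shock
# probability on the large lever, scaled per subject.
_LAT_SIGMA = 0.35
_LAT_BASE_S = 1.0
_LAT_RISK_SLOPE_S = 1.5


@dataclass
class RDTShockSchedule:
    """Per-block dependent forced-trial shocks and free-trial Bernoulli draws."""

    forced_large_shocks: list[np.ndarray]
    free_shocks: list[np.ndarray]


def build_rdt_shock_schedule(config: RDTConfig, seed) -> RDTShockSchedule:
    """Assign shock outcomes for one session.

    Forced large-lever trials get exactly ``round(n_large * p)`` shocks at
    seeded positions (an exact multiset shuffle, not rejection sampling), so
    the one-and-only-one / three-and-only-three property holds for every
    seed.  Probabilities that do not map to an integer count are a config
    error.  Free-choice outcomes are i.i.d. Bernoulli(p) draws, one per free
    trial slot, consumed only when the large lever is pressed.
    """
    rng = np.random.default_rng(seed)
    n_large = config.forced_per_block // 2
    forced, free = [], []
    for p in config.shock_probs:
        expected = p * n_large
        n_shock = round(expected)
        if abs(expected - n_shock) > 1e-9:
            raise ConfigError(
                f"shock probability {p} is not representable as a dependent "
                f"schedule over {n_large} forced large-lever trials"
            )
        mask = np.zeros(n_large, dtype=bool)
        mask[:n_shock] = True
        rng.shuffle(mask)
        forced.append(mask)
        free.append(rng.random(config.free_per_block) < p)
    return RDTShockSchedule(forced, free)


def _forced_lever_order(rng: np.random.Generator, n: int) -> list[str]:
    # one large and one small per consecutive pair, order randomized per pair
    order: list[str] = []
    for _ in range(n // 2):
        pair = ["large", "small"]
        rng.shuffle(pair)
        order.extend(pair)
    return order


def _latency(rng, agent: AgentSpec, lever: str, p_shock: float) -> float:
    median = _LAT_BASE_S + (_LAT_RISK_SLOPE_S * p_shock if lever == "large" else 0.0)
    return float(
        agent.latency_scale * median * np.exp(_LAT_SIGMA * rng.standard_normal())
    )


def rdt_choice_prob_large(agent: AgentSpec, p_shock: float, config: RDTConfig) -> float:
    """Free-choice probability of the large lever under the utility policy."""
    u_large = config.large_reward - agent.rdt.shock_aversion_kappa * p_shock
    u_small = float(config.small_reward)
    return float(expit(agent.rdt.softmax_beta_rdt * (u_large - u_small)))


def run_rdt_session(
    agent: AgentSpec, config: RDTConfig, session_seed, session: int = 1
) -> pd.DataFrame:
    """Simulate one RDT session; fully reproducible from ``session_seed``."""
    rng = np.random.default_rng(session_seed)
    schedule = build_rdt_shock_schedule(config, rng)
    rows = []
    trial = 0
    for block, p in enumerate(config.shock_probs, start=1):
        forced_shocks = iter(schedule.forced_large_shocks[block - 1])
        order = _forced_lever_order(rng, config.forced_per_block)
        for lever in order:
            trial += 1
            omitted = rng.random() < agent.rdt.omission_prob
            if omitted:
                rows.append(_rdt_row(agent, session, block, trial, "forced",
                                     lever, "none", 0, False, True, np.nan))
                if lever == "large":
                    next(forced_shocks)  # scheduled outcome unused this trial
                continue
            shock = bool(next(forced_shocks)) if lever == "large" else False
            reward = config.large_reward if lever == "large" else config.small_reward
            rows.append(_rdt_row(agent, session, block, trial, "forced", lever,
                                 lever, reward, shock, False,
                                 _latency(rng, agent, lever, p)))
        p_large = rdt_choice_prob_large(agent, p, config)
        for i in range(config.free_per_block):
            trial += 1
            omitted = rng.random() < agent.rdt.omission_prob
            if omitted:
                rows.append(_rdt_row(agent, session, block, trial, "free",
                                     "both", "none", 0, False, True, np.nan))
                continue
            choice = "large" if rng.random() < p_large else "small"
            shock = bool(schedule.free_shocks[block - 1][i]) if choice == "large" else False
            reward = config.large_reward if choice == "large" else config.small_reward
            rows.append(_rdt_row(agent, session, block, trial, "free", "both",
                                 choice, reward, shock, False,
                                 _latency(rng, agent, choice, p)))
    return pd.DataFrame(rows)


def _rdt_row(agent, session, block, trial, trial_type, offered, choice,
             reward, shock, omitted, latency):
    return {
        "task": "RDT",
        "subject_id": agent.subject_id,
        "session": session,
        "block": block,
        "trial": trial,
        "trial_type": trial_type,
        "lever_offered": offered,
        "choice": choice,
        "reward": int(reward),
        "shock": bool(shock),
        "omitted": bool(omitted),
        "latency": latency,
    }


# ---------------------------------------------------------------------------
# probabilistic reversal learning

LEVERS = ("left", "right")


class PRLState(NamedTuple):
    trial: int
    correct_side: str  # engine-private; the default learning policy ignores it


class PRLPolicy(Protocol):
    def reset(self, rng: np.random.Generator) -> None: ...
    def choose(self, rng: np.random.Generator, state: PRLState) -> Optional[str]: ...
    def observe(self, lever: str, reward: int) -> None: ...


class QLearningPolicy:
    """Delta-rule/softmax agent over the two physical levers."""

    def __init__(self, params: RLParams, omission_prob: float = 0.0):
        if not 0.0 <= omission_prob < 1.0:
            raise ValueError("omission_prob must be in [0, 1)")
        self.params = params
        self.omission_prob = omission_prob
        self.V = initial_values()

    def reset(self, rng) -> None:
        self.V = initial_values()

    def choose(self, rng, state: PRLState) -> Optional[str]:
        if self.omission_prob and rng.random() < self.omission_prob:
            return None
        p = choice_probabilities(self.V, self.params.beta)
        return LEVERS[int(rng.random() >= p[0])]

    def observe(self, lever: str, reward: int) -> None:
        self.V = update_value(self.V, LEVERS.index(lever), reward, self.params.alpha)


class OmniscientPolicy:
    """Always presses the currently correct lever (testing aid)."""

    def reset(self, rng) -> None:
        pass

    def choose(self, rng, state: PRLState) -> Optional[str]:
        return state.correct_side

    def observe(self, lever: str, reward: int) -> None:
        pass


class ScriptedPolicy:
    """Plays back a fixed choice sequence (None = omission); testing aid."""

    def __init__(self, choices: Sequence[Optional[str]]):
        self.choices = list(choices)
        self._i = 0

    def reset(self, rng) -> None:
        self._i = 0

    def choose(self, rng, state: PRLState) -> Optional[str]:
        c = self.choices[self._i]
        self._i += 1
        return c

    def observe(self, lever: str, reward: int) -> None:
        pass


def run_prl_session(
    policy: PRLPolicy,
    config: PRLConfig = PRLConfig(),
    seed=0,
    agent: AgentSpec | None = None,
    session: int = 1,
) -> tuple[pd.DataFrame, list[int]]:
    """Simulate one reversal-learning session.

    Returns the trial log (exactly ``n_trials`` rows) and the list of trial
    indices (1-based) on which a reversal was triggered.  The
    consecutive-correct counter resets on any incorrect choice or omission.
    """
    rng = np.random.default_rng(seed)
    policy.reset(rng)
    correct_side = LEVERS[int(rng.integers(2))]
    consecutive = 0
    reversals: list[int] = []
    rows = []
    subject = agent.subject_id if agent is not None else "test"
    lat_scale = agent.latency_scale if agent is not None else 1.0
    for t in range(1, config.n_trials + 1):
        choice = policy.choose(rng, PRLState(t, correct_side))
        if choice is None:
            consecutive = 0
            rows.append(_prl_row(subject, session, t, "none", correct_side,
                                 False, 0, True, np.nan))
            continue
        correct = choice == correct_side
        p_rew = config.p_reward_correct if correct else config.p_reward_incorrect
        reward = int(rng.random() < p_rew)
        policy.observe(choice, reward)
        latency = float(lat_scale * np.exp(_LAT_SIGMA * rng.standard_normal()))
        rows.append(_prl_row(subject, session, t, choice, correct_side,
                             correct, reward, False, latency))
        if correct:
            consecutive += 1
            if consecutive >= config.reversal_criterion:
                correct_side = LEVERS[1 - LEVERS.index(correct_side)]
                reversals.append(t)
                consecutive = 0
        else:
            consecutive = 0
    return pd.DataFrame(rows), reversals


def _prl_row(subject, session, trial, lever, correct_side, correct, reward,
             omitted, latency):
    return {
        "task": "PRL",
        "subject_id": subject,
        "session": session,
        "trial": trial,
        "choice_lever": lever,
        "correct_side": correct_side,
        "correct": bool(correct),
        "reward": int(reward),
        "omitted": bool(omitted),
        "latency": latency,
    }


# ---------------------------------------------------------------------------
# progressive ratio


def required_presses(r: int) -> int:
    """Presses needed to earn reward ordinal ``r``: N = r(r+1)(r+2)/6.

    The product of three consecutive integers is divisible by 6, so the
    result is always an exact integer (1, 4, 10, 20, 35, 56, 84, 120, 165...).
    """
    if not float(r).is_integer() or r < 1:
        raise ValueError(f"reward ordinal must be an integer >= 1, got {r!r}")
    r = int(r)
    return r * (r + 1) * (r + 2) // 6


@dataclass
class PRSessionResult:
    presses: int
    rewards: int
    breakpoint: int  # press requirement of the last completed ratio; 0 if none
    duration_min: float


def run_pr_session(
    agent: AgentSpec | PRPersistence,
    config: PRConfig = PRConfig(),
    seed=0,
    max_rewards: int | None = None,
) -> PRSessionResult:
    """Simulate one progressive-ratio session.

    Presses arrive as a Poisson process at ``base_rate``/min until an
    exponential giving-up time (hazard ``giving_up_hazard``/min) elapses; the
    session ends when ``giving_up_window_min`` passes without a reward or the
    session cap is reached.  ``max_rewards`` truncates the session for exact
    bookkeeping tests.
    """
    pr = agent.pr if isinstance(agent, AgentSpec) else agent
    rng = np.random.default_rng(seed)
    quit_t = np.inf if pr.giving_up_hazard == 0 else rng.exponential(1.0 / pr.giving_up_hazard)
    t = 0.0
    presses = rewards = 0
    toward = 0
    last_reward_t = 0.0
    while True:
        if pr.base_rate == 0:
            t = min(last_reward_t + config.giving_up_window_min, config.session_cap_min)
            break
        t_next = t + rng.exponential(1.0 / pr.base_rate)
        session_end = min(last_reward_t + config.giving_up_window_min,
                          config.session_cap_min)
        if t_next > quit_t or t_next > session_end:
            # pressing has stopped; the session runs out the giving-up window
            t = session_end
            break
        t = t_next
        presses += 1
        toward += 1
        if toward >= required_presses(rewards + 1):
            rewards += 1
            toward = 0
            last_reward_t = t
            if max_rewards is not None and rewards >= max_rewards:
                break
    breakpoint_ = required_presses(rewards) if rewards >= 1 else 0
    return PRSessionResult(presses, rewards, breakpoint_, float(t))


# ---------------------------------------------------------------------------
# shock-reactivity staircase


class StaircaseNonTerminatingError(RuntimeError):
    pass


class DeterministicFlinchObserver:
    """Flinches iff amplitude >= threshold (testing aid)."""

    def __init__(self, threshold: float):
        self.threshold = threshold

    def __call__(self, amp: float, rng) -> bool:
        return amp >= self.threshold - 1e-9


class LogisticFlinchObserver:
    """Stochastic psychometric observer: P(flinch) = logistic((amp-mu)/sigma)."""

    def __init__(self, mu: float, sigma: float):
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        self.mu = mu
        self.sigma = sigma

    def __call__(self, amp: float, rng) -> bool:
        return bool(rng.random() < expit((amp - self.mu) / self.sigma))


@dataclass
class StaircaseResult:
    flinch_amps: list[float]  # the flinch intensities used for the threshold
    threshold: float  # mean of flinch_amps, uA
    n_shocks_delivered: int


def run_staircase(
    observer: Callable[[float, np.random.Generator], bool],
    config: StaircaseConfig = StaircaseConfig(),
    seed=0,
) -> StaircaseResult:
    """Run the up/down flinch staircase.

    Amplitude starts at ``start_amp`` and steps up after each non-flinch and
    down after each flinch (never below ``start_amp``), until at least
    ``min_flinches`` flinches have occurred and the last delivery was a
    non-flinch.  The threshold is the mean of the first ``min_flinches``
    flinch amplitudes.  If the observer flinches at the floor once enough
    flinches are recorded the run terminates there (boundary case: threshold
    equals the floor).  An observer that never flinches below ``max_amp``
    raises :class:`StaircaseNonTerminatingError`.
    """
    rng = np.random.default_rng(seed)
    amp = float(config.start_amp)
    flinches: list[float] = []
    delivered = 0
    while True:
        f = bool(observer(amp, rng))
        delivered += 1
        if f:
            flinches.append(amp)
        if len(flinches) >= config.min_flinches:
            if not f:
                break
            if amp <= config.start_amp:  # flinching at the floor: stop here
                break
        if f:
            amp = max(config.start_amp, amp - config.step)
        else:
            amp = amp + config.step
            if amp > config.max_amp:
                raise StaircaseNonTerminatingError(
                    f"no flinch observed up to the {config.max_amp} uA cap"
                )
        if delivered > 10_000:
            raise StaircaseNonTerminatingError(
                "staircase failed to terminate within 10000 deliveries"
            )
    used = flinches[: config.min_flinches]
    return StaircaseResult(used, float(np.mean(used)), delivered)
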