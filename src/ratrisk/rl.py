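"""Rescorla-Wagner delta-rule learning with softmax choice, and per-session
maximum-likelihood estimation of its parameters.

The model tracks an associative value :math:`V^k` for each of two physical
levers (left/right), initialized to zero at the start of every session.  After
a choice of option ``k`` earning reward ``r`` (0 or 1), the chosen option's
value is updated by the delta rule

.. math:: V^k_{t+1} = V^k_t + \\alpha (r_t - V^k_t),

where the learning rate ``alpha`` lies in [0, 1] (0 = no learning, 1 = instant
learning).  Choice probabilities follow a softmax over the current values with
inverse temperature ``beta`` in [0, inf): ``beta = 0`` is random choice, large
``beta`` deterministically picks the highest-value option.  The session
likelihood is a product of Bernoulli terms, one per (non-omitted) trial,
evaluated in log space.

``fit_session`` maximizes the session log-likelihood over bounded
``(alpha, beta)`` with a multi-start quasi-Newton optimizer.  The inverse
temperature is capped at ``beta_max`` (default 50): beyond near-deterministic
choice the likelihood is flat in ``beta`` and the cap keeps fits comparable
across sessions.  A probability floor of 1e-12 inside the log prevents -inf at
pathological parameter corners; on well-posed data it never binds at the
optimum (tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

PROB_FLOOR = 1e-12
DEFAULT_BETA_MAX = 50.0
N_OPTIONS = 2  # physical levers: 0 = left, 1 = right


@dataclass(frozen=True)
class RLParams:
    """Learning rate and inverse temperature, bounds enforced at construction."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def initial_values(n_options: int = N_OPTIONS) -> np.ndarray:
    """Associative values at session start (all zero: no information yet)."""
    return np.zeros(n_options, dtype=float)


def update_value(V: np.ndarray, k: int, r: int, alpha: float) -> np.ndarray:
    """Delta-rule update of the chosen option's value; returns a new array."""
    if r not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {r!r}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    V_new = np.array(V, dtype=float, copy=True)
    V_new[k] = V_new[k] + alpha * (r - V_new[k])
    return V_new


def choice_probabilities(V: np.ndarray, beta: float) -> np.ndarray:
    """Softmax action probabilities at inverse temperature ``beta``.

    Overflow-safe (values are shifted by their maximum, which leaves the
    softmax invariant) and normalized to sum to one.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = beta * np.asarray(V, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class ChoiceData:
    """One session's choice/reward vectors with omitted trials excluded.

    ``choices`` holds the chosen option index per trial (0 = left, 1 = right);
    ``rewards`` holds the per-trial Bernoulli reward outcome.
    """

    choices: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=int)
        if self.choices.shape != self.rewards.shape or self.choices.ndim != 1:
            raise ValueError("choices and rewards must be 1-D and equal length")
        if self.n == 0:
            raise ValueError("empty choice data")
        if not np.isin(self.choices, [0, 1]).all():
            raise ValueError("choices must be 0 (left) or 1 (right)")
        if not np.isin(self.rewards, [0, 1]).all():
            raise ValueError("rewards must be 0 or 1")

    @property
    def n(self) -> int:
        return int(self.choices.size)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "ChoiceData":
        """Build from a long-format reversal-learning trial log.

        Omitted trials carry no choice and are excluded from both the value
        updates and the likelihood.
        """
        kept = trials.loc[~trials["omitted"].astype(bool)]
        lever = kept["choice_lever"].map({"left": 0, "right": 1})
        if lever.isna().any():
            raise ValueError("non-omitted trials must have choice_lever left/right")
        return cls(lever.to_numpy(), (kept["reward"].to_numpy() > 0).astype(int))


def session_log_likelihood(data: ChoiceData, params: RLParams) -> float:
    """Log-likelihood (nats) of a session under the delta-rule/softmax model.

    The forward pass interleaves the value update with the per-trial Bernoulli
    log-probability of the observed choice; the log is taken per trial, never
    via the raw product.  With two options the softmax probability of the
    chosen lever equals the logistic of the scaled value difference, which is
    what the loop evaluates (scalar arithmetic keeps the per-session fit fast).
    """
    import math

    a, b = params.alpha, params.beta
    v = [0.0, 0.0]
    ll = 0.0
    log_floor = math.log(PROB_FLOOR)
    for c, r in zip(data.choices.tolist(), data.rewards.tolist()):
        d = b * (v[c] - v[1 - c])
        lp = -math.log1p(math.exp(-d)) if d > 0 else d - math.log1p(math.exp(d))
        ll += lp if lp > log_floor else log_floor
        v[c] += a * (r - v[c])
    return ll


def grid_log_likelihood(
    data: ChoiceData, alphas: np.ndarray, betas: np.ndarray
) -> np.ndarray:
    """Session log-likelihood on an (alpha, beta) grid, vectorized.

    With two options the softmax reduces to a logistic in the value difference
    ``d_t = V[chosen] - V[other]``, whose trajectory depends only on alpha, so
    the full grid is computed from one alpha-vectorized forward pass.  Uses
    the same probability floor as :func:`session_log_likelihood`.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    A = alphas.size
    V = np.zeros((A, N_OPTIONS))
    D = np.empty((data.n, A))
    for t, (c, r) in enumerate(zip(data.choices, data.rewards)):
        D[t] = V[:, c] - V[:, 1 - c]
        V[:, c] += alphas * (r - V[:, c])
    # log sigmoid(beta * d), floored identically to the scalar path
    M = betas[None, None, :] * D[:, :, None]
    logp = -np.logaddexp(0.0, -M)
    np.maximum(logp, np.log(PROB_FLOOR), out=logp)
    return logp.sum(axis=0)


@dataclass(frozen=True)
class FitConfig:
    """Settings for per-session maximum-likelihood fitting."""

    n_starts: int = 16
    beta_max: float = DEFAULT_BETA_MAX
    seed: int = 0
    min_trials: int = 20
    check_lattice: bool = False
    lattice_shape: tuple[int, int] = (51, 51)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.beta_max <= 0:
            raise ValueError("beta_max must be > 0")


@dataclass
class FitResult:
    params: RLParams
    log_likelihood: float
    n_starts: int
    converged: bool
    best_start_seed: int
    low_n: bool = False
    non_identifiable: bool = False
    lattice_margin: float | None = None


def fit_session(data: ChoiceData, config: FitConfig = FitConfig()) -> FitResult:
    """Bounded multi-start MLE of (alpha, beta) for one session.

    Starts are a seeded Latin hypercube over alpha in [0, 1] and beta in
    [0, 10] (the optimizer itself may move beta up to ``beta_max``),
    supplemented by the best points of a coarse likelihood grid: the surface
    is flat along the alpha = 0 and beta = 0 lines (either one makes choice
    probabilities constant), so a gradient method started far from the
    optimum can stall on that ridge, and the grid starts guarantee a start
    inside the basin of the maximum.  On log-likelihood ties within 1e-9 the
    lowest alpha, then lowest beta, wins.  Sessions whose choices and rewards
    never vary cannot constrain the parameters; they are returned flagged
    ``non_identifiable`` instead of raising.
    """
    low_n = data.n < config.min_trials
    non_ident = (
        np.unique(data.choices).size == 1 and np.unique(data.rewards).size == 1
    )

    def nll(x: np.ndarray) -> float:
        return -session_log_likelihood(data, RLParams(float(x[0]), float(x[1])))

    sampler = qmc.LatinHypercube(d=2, seed=config.seed)
    starts = list(sampler.random(config.n_starts))
    for s in starts:
        s[1] *= 10.0  # beta starts span the well-identified range

    coarse_a = np.linspace(0.0, 1.0, 51)
    coarse_b = np.linspace(0.0, config.beta_max, 51)
    coarse = grid_log_likelihood(data, coarse_a, coarse_b)
    order = np.argsort(coarse, axis=None)[::-1][:3]
    grid_starts = []
    grid_best = None
    for flat in order:
        ai, bi = np.unravel_index(flat, coarse.shape)
        grid_starts.append(np.array([coarse_a[ai], coarse_b[bi]]))
        if grid_best is None:
            grid_best = (float(coarse[ai, bi]), float(coarse_a[ai]),
                         float(coarse_b[bi]), True, -1)
    bounds = [(0.0, 1.0), (0.0, config.beta_max)]
    nm_opts = {"fatol": 1e-10, "xatol": 1e-8, "maxiter": 600}

    candidates = [grid_best]
    for i, x0 in enumerate(starts):
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        candidates.append((-float(res.fun), float(res.x[0]), float(res.x[1]),
                           bool(res.success), i))
    # the grid starts get a derivative-free polish: the quasi-Newton step can
    # stall where the projected numerical gradient vanishes on the flat ridge
    for i, x0 in enumerate(grid_starts):
        res = optimize.minimize(nll, x0, method="Nelder-Mead", bounds=bounds,
                                options=nm_opts)
        candidates.append((-float(res.fun), float(res.x[0]), float(res.x[1]),
                           bool(res.success), config.n_starts + i))
    # final local refinement from the best point found so far
    incumbent = max(candidates, key=lambda c: c[0])
    res = optimize.minimize(nll, [incumbent[1], incumbent[2]],
                            method="Nelder-Mead", bounds=bounds, options=nm_opts)
    candidates.append((-float(res.fun), float(res.x[0]), float(res.x[1]),
                       bool(res.success), incumbent[4]))
    best_ll = max(c[0] for c in candidates)
    tied = [c for c in candidates if best_ll - c[0] <= 1e-9]
    ll, alpha, beta, success, start_idx = min(tied, key=lambda c: (c[1], c[2]))

    margin = None
    if config.check_lattice:
        na, nb = config.lattice_shape
        grid = grid_log_likelihood(
            data, np.linspace(0, 1, na), np.linspace(0, config.beta_max, nb)
        )
        margin = float(ll - grid.max())

    return FitResult(
        params=RLParams(alpha, beta),
        log_likelihood=ll,
        n_starts=config.n_starts,
        converged=any(c[3] for c in candidates),
        best_start_seed=start_idx,
        low_n=low_n,
        non_identifiable=non_ident,
        lattice_margin=margin,
    )


def fit_sessions(
    logs: pd.DataFrame, config: FitConfig = FitConfig()
) -> pd.DataFrame:
    """Fit every (subject, session) group of a long-format reversal-learning
    trial log; returns a tidy parameter table."""
    rows = []
    for (subj, sess), grp in logs.groupby(["subject_id", "session"], sort=True):
        fit = fit_session(ChoiceData.from_trials(grp), config)
        rows.append(
            {
                "subject_id": subj,
                "session": sess,
                "alpha": fit.params.alpha,
                "beta": fit.params.beta,
                "log_likelihood": fit.log_likelihood,
                "n_trials": int((~grp["omitted"].astype(bool)).sum()),
                "converged": fit.converged,
                "low_n": fit.low_n,
                "non_identifiable": fit.non_identifiable,
            }
        )
    return pd.DataFrame(rows)
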