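"""Synthetic cohort generation: agents, psychometric observers, ROI series.

Every synthetic subject is an :class:`AgentSpec` bundling the generative
parameters for all four behavioral tasks plus a private seed, drawn from
per-age-group parameter distributions (:class:`CohortSpec`).  The defaults
shipped in ``defaults.yaml`` are fabricated values chosen to reproduce the
qualitative structure the downstream analyses look for; they are not
estimates from animal data.

The risky-choice generative policy is a minimal utility model: on a
free-choice trial with punishment probability ``p`` the large lever has
utility ``large_reward - kappa * p`` against the small lever's
``small_reward``, passed through a softmax at inverse temperature
``softmax_beta_rdt``.  A larger shock-aversion ``kappa`` yields the steeper
block-wise decline characteristic of aged subjects.

ROI time series are AR(1)-filtered Gaussian noise mixed through a symmetric
square root of the target correlation matrix, so the population correlation of
the generated rows equals the target exactly and the sample correlation
converges at the usual 1/sqrt(T-3) Fisher rate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .connectivity import DEFAULT_ROIS, ROITimeSeriesSet, default_group_corr
from .rl import RLParams

AGE_GROUPS = ("young", "aged")

#: stream tag mixed into a subject's seed for the ROI-series generator, so the
#: same subject seed can drive independent behavioral and imaging streams.
_ROI_STREAM = 0x526F49


@dataclass(frozen=True)
class RDTPolicy:
    """Generative free-choice policy for the risky decision-making task."""

    shock_aversion_kappa: float  # utility units per unit punishment probability
    softmax_beta_rdt: float
    omission_prob: float

    def __post_init__(self) -> None:
        if self.shock_aversion_kappa < 0:
            raise ValueError("shock_aversion_kappa must be >= 0")
        if self.softmax_beta_rdt < 0:
            raise ValueError("softmax_beta_rdt must be >= 0")
        if not 0.0 <= self.omission_prob < 1.0:
            raise ValueError("omission_prob must be in [0, 1)")


@dataclass(frozen=True)
class PRPersistence:
    """Generative pressing model for the progressive-ratio task."""

    base_rate: float  # presses per minute
    giving_up_hazard: float  # 1/min

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.giving_up_hazard < 0:
            raise ValueError("base_rate and giving_up_hazard must be >= 0")


@dataclass(frozen=True)
class StaircaseObserverParams:
    """Logistic flinch psychometric: location and spread in microamps."""

    threshold_mu: float
    slope_sigma: float

    def __post_init__(self) -> None:
        if self.slope_sigma <= 0:
            raise ValueError("slope_sigma must be > 0")


@dataclass(frozen=True)
class AgentSpec:
    subject_id: str
    age_group: str
    rdt: RDTPolicy
    rl: RLParams
    pr: PRPersistence
    staircase: StaircaseObserverParams
    locomotor_rate: float
    latency_scale: float
    seed: int

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.locomotor_rate < 0:
            raise ValueError("locomotor_rate must be >= 0")
        if self.latency_scale <= 0:
            raise ValueError("latency_scale must be > 0")


# field -> (clip lo, clip hi); omission stays < 1 and rl_alpha inside (0, 1)
# so every sampled agent is valid and identifiable.
_FIELD_CLIPS = {
    "shock_aversion_kappa": (0.0, np.inf),
    "softmax_beta_rdt": (0.0, np.inf),
    "omission_prob": (0.0, 0.95),
    "rl_alpha": (0.02, 0.98),
    "rl_beta": (0.1, 20.0),
    "pr_base_rate": (1.0, np.inf),
    "pr_giving_up_hazard": (0.01, np.inf),
    "threshold_mu": (75.0, np.inf),
    "slope_sigma": (5.0, np.inf),
    "locomotor_rate": (0.5, np.inf),
    "latency_scale": (0.3, np.inf),
}


def default_group_params() -> dict:
    """Per-group (mean, sd) distributions shipped with the package."""
    text = (
        importlib.resources.files("ratrisk").joinpath("defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


@dataclass(frozen=True)
class CohortSpec:
    n_young: int
    n_aged: int
    master_seed: int
    group_params: dict = field(default_factory=default_group_params)

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_aged < 0:
            raise ValueError("group counts must be >= 0")
        if self.n_young + self.n_aged < 1:
            raise ValueError("cohort must contain at least one subject")
        for group in AGE_GROUPS:
            if group not in self.group_params:
                raise ValueError(f"group_params missing group {group!r}")
            params = self.group_params[group]
            for name in _FIELD_CLIPS:
                if name not in params:
                    raise ValueError(f"group_params[{group!r}] missing field {name!r}")
                spec = params[name]
                if spec["sd"] < 0:
                    raise ValueError(
                        f"group_params[{group!r}][{name!r}]: sd must be >= 0, "
                        f"got {spec['sd']}"
                    )


def _draw_field(rng: np.random.Generator, spec: dict, name: str) -> float:
    lo, hi = _FIELD_CLIPS[name]
    return float(np.clip(rng.normal(spec["mean"], spec["sd"]), lo, hi))


def make_cohort(spec: CohortSpec) -> list[AgentSpec]:
    """Draw a cohort of agents; a pure function of the spec.

    Per-subject seeds are derived from the master seed through a seed
    sequence keyed on the subject index, so they are distinct and
    reproducible.
    """
    rng = np.random.default_rng(spec.master_seed)
    agents: list[AgentSpec] = []
    seeds_seen: set[int] = set()
    i = 0
    for group, n in (("young", spec.n_young), ("aged", spec.n_aged)):
        gp = spec.group_params[group]
        for _ in range(n):
            draws = {name: _draw_field(rng, gp[name], name) for name in _FIELD_CLIPS}
            seed = int(
                np.random.SeedSequence([spec.master_seed, i]).generate_state(1)[0]
                % (2**31)
            )
            while seed in seeds_seen:  # vanishingly unlikely, but guaranteed distinct
                seed = (seed + 1) % (2**31)
            seeds_seen.add(seed)
            agents.append(
                AgentSpec(
                    subject_id=f"{group[0].upper()}{i:03d}",
                    age_group=group,
                    rdt=RDTPolicy(
                        draws["shock_aversion_kappa"],
                        draws["softmax_beta_rdt"],
                        draws["omission_prob"],
                    ),
                    rl=RLParams(draws["rl_alpha"], draws["rl_beta"]),
                    pr=PRPersistence(
                        draws["pr_base_rate"], draws["pr_giving_up_hazard"]
                    ),
                    staircase=StaircaseObserverParams(
                        draws["threshold_mu"], draws["slope_sigma"]
                    ),
                    locomotor_rate=draws["locomotor_rate"],
                    latency_scale=draws["latency_scale"],
                    seed=seed,
                )
            )
            i += 1
    return agents


def agents_to_frame(agents: list[AgentSpec]) -> pd.DataFrame:
    """Flatten a cohort to a tidy per-subject manifest table."""
    return pd.DataFrame(
        {
            "subject_id": a.subject_id,
            "age_group": a.age_group,
            "shock_aversion_kappa": a.rdt.shock_aversion_kappa,
            "softmax_beta_rdt": a.rdt.softmax_beta_rdt,
            "omission_prob": a.rdt.omission_prob,
            "rl_alpha": a.rl.alpha,
            "rl_beta": a.rl.beta,
            "pr_base_rate": a.pr.base_rate,
            "pr_giving_up_hazard": a.pr.giving_up_hazard,
            "threshold_mu": a.staircase.threshold_mu,
            "slope_sigma": a.staircase.slope_sigma,
            "locomotor_rate": a.locomotor_rate,
            "latency_scale": a.latency_scale,
            "seed": a.seed,
        }
        for a in agents
    )


def make_roi_timeseries(
    subject: AgentSpec,
    rois=DEFAULT_ROIS,
    T: int = 300,
    target_corr: np.ndarray | None = None,
    ar1: float = 0.3,
) -> ROITimeSeriesSet:
    """Generate one subject's ROI x T matrix with a known correlation matrix.

    Rows are stationary unit-variance AR(1) processes (coefficient ``ar1``)
    mixed through the symmetric square root of ``target_corr``, so the
    population cross-ROI correlation equals ``target_corr`` exactly.
    Deterministic given the subject's seed.
    """
    rois = tuple(rois)
    if target_corr is None:
        target_corr = default_group_corr(subject.age_group, rois)
    C = np.asarray(target_corr, dtype=float)
    k = len(rois)
    if C.shape != (k, k):
        raise ValueError(f"target_corr must be {k}x{k}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("target_corr must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("target_corr must have a unit diagonal")
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError(
            f"target_corr is not positive semidefinite "
            f"(smallest eigenvalue {w.min():.3e})"
        )
    if T < 30:
        raise ValueError("need T >= 30")
    if not abs(ar1) < 1:
        raise ValueError("|ar1| must be < 1")

    root = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    rng = np.random.default_rng([subject.seed, _ROI_STREAM])
    eps = rng.standard_normal((k, T))
    # stationary unit-variance AR(1): x_0 = eps_0, x_t = ar1*x_{t-1} + s*eps_t
    from scipy.signal import lfilter

    u = np.sqrt(1.0 - ar1**2) * eps
    u[:, 0] = eps[:, 0]
    X = lfilter([1.0], [1.0, -ar1], u, axis=1)
    return ROITimeSeriesSet(subject.subject_id, rois, root @ X)
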