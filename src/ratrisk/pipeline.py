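"""End-to-end orchestration: cohort -> task simulation -> fitting/metrics ->
connectivity -> report.

All randomness flows from named child seeds derived from the run's master
seed: ``derive_seed(master, label, *indices)`` hashes the stage label and any
per-subject/per-session indices into a seed sequence, so identical configs
produce byte-identical outputs while every stage and subject gets an
independent stream.

The risky-choice stage mirrors the training protocol: sessions are simulated
(for the whole cohort in lockstep) until the three-session stability criterion
passes, up to a cap of 45 sessions, after which the last three sessions are
used with a warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from . import metrics
from .cohort import AgentSpec, CohortSpec, agents_to_frame, make_cohort, make_roi_timeseries
from .connectivity import DEFAULT_ROIS, default_group_corr
from .rl import FitConfig, fit_sessions
from .tasks import (
    LogisticFlinchObserver,
    PRConfig,
    PRLConfig,
    QLearningPolicy,
    RDTConfig,
    StaircaseConfig,
    required_presses,
    run_pr_session,
    run_prl_session,
    run_rdt_session,
    run_staircase,
)

logger = logging.getLogger("ratrisk")

#: per-trial omission probability in the reversal task (fabricated, scaled to
#: the near-zero omission percentages seen in that task).
PRL_OMISSION_PROB = {"young": 0.005, "aged": 0.015}


def derive_seed(master_seed: int, label: str, *indices: int) -> int:
    """Deterministic child seed for a named stage (and optional indices)."""
    key = [int(master_seed), zlib.crc32(label.encode())] + [int(i) for i in indices]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ConnectivitySettings:
    rois: tuple[str, ...] = DEFAULT_ROIS
    n_timepoints: int = 300
    ar1: float = 0.3
    n_boot: int = 1000
    tr_s: float = 2.0


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec
    rdt: RDTConfig = RDTConfig()
    prl: PRLConfig = PRLConfig()
    pr: PRConfig = PRConfig()
    staircase: StaircaseConfig = StaircaseConfig()
    n_prl_sessions: int = 8
    n_pr_sessions: int = 7
    rdt_min_sessions: int = 3
    rdt_session_cap: int = 45
    fit: FitConfig = FitConfig()
    connectivity: ConnectivitySettings = ConnectivitySettings()
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.n_prl_sessions < 1 or self.n_pr_sessions < 1:
            raise ValueError("session counts must be >= 1")
        if not 3 <= self.rdt_min_sessions <= self.rdt_session_cap:
            raise ValueError("need 3 <= rdt_min_sessions <= rdt_session_cap")

    @property
    def master_seed(self) -> int:
        return self.cohort.master_seed


# ---------------------------------------------------------------------------
# stages


def simulate_rdt_to_stability(
    agents: list[AgentSpec], config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Run RDT sessions for the whole cohort until choice is stable.

    After each session beyond the minimum, the three-session stability
    criterion is evaluated on the last three sessions; training stops when it
    passes or at the session cap (then the last three sessions are used with a
    logged warning).
    """
    seed = config.master_seed
    logs: list[pd.DataFrame] = []
    session = 0
    stable = False
    while session < config.rdt_session_cap:
        session += 1
        for i, agent in enumerate(agents):
            logs.append(
                run_rdt_session(
                    agent, config.rdt, derive_seed(seed, "rdt", i, session), session
                )
            )
        if session >= config.rdt_min_sessions:
            trials = pd.concat(logs, ignore_index=True)
            summaries = metrics.block_choice_summary(trials)
            last3 = summaries[summaries["session"] > session - 3]
            try:
                stable, _ = metrics.stability_check(last3)
            except ValueError:  # too few usable subjects this round
                stable = False
            if stable:
                break
    if not stable:
        logger.warning(
            "stability not reached within %d sessions; using the last three",
            config.rdt_session_cap,
        )
    trials = pd.concat(logs, ignore_index=True)
    return trials, {"n_sessions": session, "stable": stable}


def simulate_staircases(agents, config: RunConfig) -> pd.DataFrame:
    rows = []
    for i, agent in enumerate(agents):
        obs = LogisticFlinchObserver(agent.staircase.threshold_mu,
                                     agent.staircase.slope_sigma)
        res = run_staircase(obs, config.staircase,
                            derive_seed(config.master_seed, "staircase", i))
        rows.append({"subject_id": agent.subject_id, "age_group": agent.age_group,
                     "shock_threshold": res.threshold,
                     "n_shocks_delivered": res.n_shocks_delivered})
    return pd.DataFrame(rows)


def simulate_prl(agents, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All reversal-learning sessions; returns (trials, per-session summary)."""
    logs, summaries = [], []
    for i, agent in enumerate(agents):
        for s in range(1, config.n_prl_sessions + 1):
            policy = QLearningPolicy(agent.rl, PRL_OMISSION_PROB[agent.age_group])
            trials, reversals = run_prl_session(
                policy, config.prl, derive_seed(config.master_seed, "prl", i, s),
                agent=agent, session=s,
            )
            logs.append(trials)
            summ = metrics.reversal_summary(trials, reversals, config.prl.n_trials)
            summaries.append({
                "subject_id": agent.subject_id, "age_group": agent.age_group,
                "session": s, "reversals_raw": summ.reversals_raw,
                "trials_completed": summ.trials_completed,
                "reversals_corrected": summ.reversals_corrected,
                "trials_per_reversal": summ.trials_per_reversal,
            })
    return pd.concat(logs, ignore_index=True), pd.DataFrame(summaries)


def simulate_pr(agents, config: RunConfig) -> pd.DataFrame:
    rows = []
    for i, agent in enumerate(agents):
        for s in range(1, config.n_pr_sessions + 1):
            res = run_pr_session(agent, config.pr,
                                 derive_seed(config.master_seed, "pr", i, s))
            rows.append({"subject_id": agent.subject_id,
                         "age_group": agent.age_group, "session": s,
                         "presses": res.presses, "rewards": res.rewards,
                         "breakpoint": res.breakpoint})
    return pd.DataFrame(rows)


def simulate_locomotor(agents, rdt_trials: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Poisson activity counts per inter-trial interval and per shock.

    Only the per-subject means feed downstream summaries; shock-period
    activity is undefined for subjects who never received a shock.
    """
    shocks = rdt_trials.groupby("subject_id")["shock"].sum()
    n_trials = rdt_trials.groupby("subject_id").size()
    rows = []
    for i, agent in enumerate(agents):
        rng = np.random.default_rng(derive_seed(config.master_seed, "locomotor", i))
        n_iti = int(n_trials.get(agent.subject_id, 0))
        iti = rng.poisson(agent.locomotor_rate, size=max(n_iti, 1)).mean()
        n_shock = int(shocks.get(agent.subject_id, 0))
        shock_act = (
            rng.poisson(0.2 * agent.locomotor_rate, size=n_shock).mean()
            if n_shock else np.nan
        )
        omissions = rdt_trials[rdt_trials["subject_id"] == agent.subject_id]
        rows.append({
            "subject_id": agent.subject_id, "age_group": agent.age_group,
            "iti_activity": float(iti), "shock_activity": float(shock_act),
            "omissions_per_session": float(
                omissions.groupby("session")["omitted"].sum().mean()
            ) if len(omissions) else np.nan,
        })
    return pd.DataFrame(rows)


def connectivity_stage(agents, config: RunConfig) -> pd.DataFrame:
    cs = config.connectivity
    tables = []
    for i, agent in enumerate(agents):
        ts = make_roi_timeseries(
            agent, cs.rois, cs.n_timepoints,
            default_group_corr(agent.age_group, cs.rois), cs.ar1,
        )
        ts.tr = cs.tr_s
        tables.append(conn_mod.pairwise_bootstrap_pearson(
            ts, n_boot=cs.n_boot,
            seed=derive_seed(config.master_seed, "bootstrap", i),
        ))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# full study


def run_full_study(config: RunConfig) -> dict:
    """Execute every stage in order and return the bundle of result tables.

    Identical configs give identical bundles.  Group-contrast stages are
    skipped with a warning when either age group is empty.  When
    ``config.outdir`` is set all tables, the report, and a manifest (config
    hash + seeds) are written there.
    """
    agents = make_cohort(config.cohort)
    labels = pd.Series(
        {a.subject_id: a.age_group for a in agents}, name="age_group"
    )
    two_groups = labels.nunique() == 2
    bundle: dict = {"agents": agents_to_frame(agents)}

    logger.info("stage 1/6: risky decision-making task (%d subjects)", len(agents))
    rdt_trials, rdt_info = simulate_rdt_to_stability(agents, config)
    bundle["rdt_trials"] = rdt_trials
    summaries = metrics.block_choice_summary(rdt_trials)
    last3 = summaries[summaries["session"] > rdt_info["n_sessions"] - 3]
    bundle["rdt_block_summary"] = last3
    wsls = [
        dict(subject_id=s, age_group=labels[s],
             **dataclasses.asdict(metrics.rdt_win_stay_lose_shift(g)))
        for s, g in rdt_trials.groupby("subject_id")
    ]
    bundle["rdt_ws_ls"] = pd.DataFrame(wsls)
    bundle["forced_latency"] = metrics.forced_latency_block_table(
        rdt_trials[rdt_trials["session"] > rdt_info["n_sessions"] - 3]
    )
    bundle["free_latency"] = metrics.free_latency_by_lever(
        rdt_trials[rdt_trials["session"] > rdt_info["n_sessions"] - 3]
    )
    bundle["locomotor"] = simulate_locomotor(agents, rdt_trials, config)

    logger.info("stage 2/6: shock-reactivity staircase")
    bundle["staircase"] = simulate_staircases(agents, config)

    logger.info("stage 3/6: probabilistic reversal learning")
    prl_trials, prl_summary = simulate_prl(agents, config)
    bundle["prl_trials"] = prl_trials
    bundle["prl_summary"] = prl_summary
    bundle["prl_ws_ls"] = pd.DataFrame(
        dict(subject_id=s, age_group=labels[s],
             **dataclasses.asdict(metrics.prl_win_stay_lose_shift(g)))
        for s, g in prl_trials.groupby("subject_id")
    )

    logger.info("stage 4/6: progressive ratio")
    bundle["pr_sessions"] = simulate_pr(agents, config)

    logger.info("stage 5/6: reinforcement-learning fits")
    bundle["rl_fits"] = fit_sessions(prl_trials, config.fit)

    logger.info("stage 6/6: functional connectivity")
    conn = connectivity_stage(agents, config)
    bundle["connectivity_edges"] = conn

    # cross-task subject table
    scores = metrics.risk_scores(last3)
    subject_table = (
        bundle["staircase"][["subject_id", "age_group", "shock_threshold"]]
        .merge(scores, on="subject_id")
        .merge(
            prl_summary.groupby("subject_id")["reversals_corrected"]
            .mean().rename("mean_reversals"), on="subject_id",
        )
        .merge(
            bundle["pr_sessions"].groupby("subject_id")["breakpoint"]
            .mean().rename("mean_breakpoint"), on="subject_id",
        )
    )
    bundle["subject_table"] = subject_table

    if two_groups and subject_table.groupby("age_group").size().min() >= 4:
        bundle["cross_task_correlations"] = metrics.cross_task_correlations(subject_table)
    else:
        warnings.warn("skipping cross-task correlations: a group is too small")
    if two_groups and labels.value_counts().min() >= 2:
        result = conn_mod.group_connectivity_analysis(conn, labels)
        bundle["connectivity_anova"] = result["anova"]
        bundle["connectivity_posthoc"] = result["posthoc"]
        bundle["behavior_connectivity"] = conn_mod.behavior_connectivity_correlation(
            scores.reindex(labels.index), conn, labels
        )
    else:
        warnings.warn("skipping group connectivity contrast: need two groups")

    bundle["report"] = build_report(bundle, rdt_info, config)
    if config.outdir:
        write_bundle(bundle, config)
    return bundle


def build_report(bundle: dict, rdt_info: dict, config: RunConfig) -> dict:
    """Aggregate group-level summary (block means +/- SEM and task means)."""
    labels = bundle["agents"].set_index("subject_id")["age_group"]
    summ = bundle["rdt_block_summary"].copy()
    summ["age_group"] = summ["subject_id"].map(labels)
    per_subj = summ.groupby(["age_group", "subject_id", "block"])["p_large"].mean()
    block_means = {
        group: {
            int(b): {"mean": float(v.mean()), "sem": float(v.sem()) if len(v) > 1 else None}
            for b, v in g.groupby("block")
        }
        for group, g in per_subj.groupby("age_group")
    }
    conn = bundle["connectivity_edges"].copy()
    conn["age_group"] = conn["subject_id"].map(labels)
    mean_z = conn.groupby("age_group")["z"].mean().to_dict()
    report = {
        "rdt": {
            "n_sessions": rdt_info["n_sessions"],
            "stable": rdt_info["stable"],
            "p_large_by_block": block_means,
        },
        "staircase": bundle["staircase"].groupby("age_group")["shock_threshold"]
        .mean().to_dict(),
        "prl": bundle["prl_summary"].groupby("age_group")["reversals_corrected"]
        .mean().to_dict(),
        "pr_breakpoint": bundle["pr_sessions"].groupby("age_group")["breakpoint"]
        .mean().to_dict(),
        "connectivity_mean_z": {k: float(v) for k, v in mean_z.items()},
    }
    if "connectivity_posthoc" in bundle:
        ph = bundle["connectivity_posthoc"]
        report["connectivity_significant_pairs"] = ph.loc[
            ph["significant"], "pair"
        ].tolist()
    return report


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    (out / "report.json").write_text(json.dumps(bundle["report"], indent=2))
    manifest = {
        "master_seed": config.master_seed,
        "config_sha256_16": config_hash(config),
        "n_young": config.cohort.n_young,
        "n_aged": config.cohort.n_aged,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# headline pattern (reduced end-to-end check)


def headline_pattern(
    master_seed: int,
    n_young: int = 20,
    n_aged: int = 18,
    n_sessions: int = 3,
    rdt_config: RDTConfig = RDTConfig(),
    conn_settings: ConnectivitySettings = ConnectivitySettings(),
) -> dict:
    """Evaluate the study's qualitative ground-truth pattern for one seed.

    Simulates the risky-choice sessions and ROI series for a default cohort
    and checks: group-mean risky choice declines across the punishment blocks
    (2-5) in both groups, the aged mean sits below the young mean in blocks
    3-5, and mean Fisher-z connectivity is higher in the aged group.
    """
    spec = CohortSpec(n_young=n_young, n_aged=n_aged, master_seed=master_seed)
    agents = make_cohort(spec)
    labels = pd.Series({a.subject_id: a.age_group for a in agents})
    logs = [
        run_rdt_session(a, rdt_config, derive_seed(master_seed, "rdt", i, s), s)
        for i, a in enumerate(agents)
        for s in range(1, n_sessions + 1)
    ]
    summ = metrics.block_choice_summary(pd.concat(logs, ignore_index=True))
    summ["age_group"] = summ["subject_id"].map(labels)
    means = summ.groupby(["age_group", "block"])["p_large"].mean().unstack()

    declining = all(
        means.loc[g, b + 1] < means.loc[g, b]
        for g in ("young", "aged")
        for b in (2, 3, 4)
    )
    aged_below = all(means.loc["aged", b] < means.loc["young", b] for b in (3, 4, 5))

    z_means = {}
    for group in ("young", "aged"):
        zs = []
        for i, a in enumerate(agents):
            if a.age_group != group:
                continue
            ts = make_roi_timeseries(
                a, conn_settings.rois, conn_settings.n_timepoints,
                default_group_corr(group, conn_settings.rois), conn_settings.ar1,
            )
            R = np.corrcoef(ts.data)
            iu = np.triu_indices_from(R, k=1)
            zs.append(np.arctanh(np.clip(R[iu], -0.999999, 0.999999)).mean())
        z_means[group] = float(np.mean(zs))

    return {
        "declining_risky_choice": bool(declining),
        "aged_below_young_blocks_3_5": bool(aged_below),
        "aged_connectivity_above_young": bool(z_means["aged"] > z_means["young"]),
        "pass": bool(declining and aged_below and z_means["aged"] > z_means["young"]),
        "block_means": means.to_dict(),
        "mean_z": z_means,
    }


# ---------------------------------------------------------------------------
# trial-log validation


@dataclass
class ValidationReport:
    ok: bool
    violations: list[tuple[int, str]] = field(default_factory=list)


def validate_trial_log(
    trials: pd.DataFrame | str | Path, rdt_config: RDTConfig | None = None
) -> ValidationReport:
    """Schema and invariant checks for a trial log (path or DataFrame).

    Checks column presence, the omission invariants (no choice, no reward, no
    shock), that shocks occur only on large-lever presses, and — when an RDT
    config is supplied — the per-block forced/free trial counts.
    Violations are reported with their row numbers.
    """
    from .io import RDT_COLUMNS, PRL_COLUMNS, read_trials

    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)
    violations: list[tuple[int, str]] = []
    task = str(trials["task"].iloc[0]) if len(trials) else "RDT"
    schema = RDT_COLUMNS if task == "RDT" else PRL_COLUMNS
    missing = set(schema) - set(trials.columns)
    if missing:
        return ValidationReport(False, [(-1, f"missing columns {sorted(missing)}")])

    choice_col = "choice" if task == "RDT" else "choice_lever"
    for idx, row in trials.iterrows():
        if row["omitted"]:
            if row[choice_col] != "none" or row["reward"] != 0 or row.get("shock", False):
                violations.append((idx, "omitted trial with a choice/reward/shock"))
        elif task == "RDT" and row["shock"] and row["choice"] != "large":
            violations.append((idx, "shock delivered on a non-large-lever press"))

    if task == "RDT" and rdt_config is not None:
        counts = trials.groupby(["subject_id", "session", "block", "trial_type"]).size()
        for (subj, sess, block, ttype), n in counts.items():
            want = (
                rdt_config.forced_per_block
                if ttype == "forced"
                else rdt_config.free_per_block
            )
            if n != want:
                violations.append(
                    (-1, f"{subj} session {sess} block {block}: "
                         f"{n} {ttype} trials, expected {want}")
                )
    return ValidationReport(not violations, violations)
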