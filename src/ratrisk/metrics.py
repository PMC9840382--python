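"""Derived behavioral statistics from long-format trial logs.

Covers the block-wise risky-choice summaries and their variance-stabilizing
arcsine transform, win-stay/lose-shift conditional probabilities for both the
risky-choice and reversal-learning tasks, the omission-corrected reversal
rate, forced/free response-latency tables (with the prior-block extrapolation
rule for fully omitted forced blocks), the three-session stability criterion,
and cross-task Spearman correlations.

Win-stay/lose-shift conventions (documented choices where the procedure
leaves room): adjacency is over consecutive free-choice trials within a
session, forced-choice trials are transparent (skipped), and an omission on
either member of a pair breaks adjacency.  In the reversal task the stay/shift
identity of the follower is judged against the correct lever in force on the
predecessor trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import rm_anova_two_way


def arcsine_transform(p):
    """Variance-stabilizing arcsin(sqrt(p)) for proportions in [0, 1] (radians)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if out.ndim == 0 else out


def block_choice_summary(rdt_trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject/session/block free-choice counts and large-lever proportion."""
    free = rdt_trials[rdt_trials["trial_type"] == "free"]
    done = free[~free["omitted"]]
    g = done.groupby(["subject_id", "session", "block"])
    out = g.agg(
        n_free=("choice", "size"),
        n_large=("choice", lambda c: int((c == "large").sum())),
    ).reset_index()
    # blocks where every free trial was omitted still appear, with NaN p
    full = (
        free.groupby(["subject_id", "session", "block"])
        .size()
        .rename("n_offered")
        .reset_index()
    )
    out = full.merge(out, on=["subject_id", "session", "block"], how="left")
    out["n_free"] = out["n_free"].astype(float).fillna(0).astype(int)
    out["n_large"] = out["n_large"].astype(float).fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        out["p_large"] = np.where(
            out["n_free"] > 0, out["n_large"] / out["n_free"], np.nan
        )
    out["p_large_arcsine"] = [
        arcsine_transform(p) if np.isfinite(p) else np.nan for p in out["p_large"]
    ]
    return out.drop(columns="n_offered")


@dataclass
class WinStayLoseShift:
    ws: float  # NaN when no win opportunities
    ls: float  # NaN when no loss opportunities
    n_win_opportunities: int
    n_loss_opportunities: int


def _free_pairs(session_trials: pd.DataFrame):
    """Consecutive free-choice trial pairs of one session, both non-omitted."""
    free = session_trials[session_trials["trial_type"] == "free"].sort_values("trial")
    rows = list(free.itertuples(index=False))
    for prev, nxt in zip(rows, rows[1:]):
        if not prev.omitted and not nxt.omitted:
            yield prev, nxt


def rdt_win_stay_lose_shift(trials: pd.DataFrame) -> WinStayLoseShift:
    """Win-stay / lose-shift over a subject's risky-choice free trials.

    A "win" is a large-lever press that earned the large reward with no shock;
    staying means pressing the large lever on the next free-choice trial.  A
    "loss" is a shocked large-lever press; shifting means pressing the small
    lever next.  Counts pool across sessions; adjacency never crosses a
    session boundary.
    """
    ws_n = ws_d = ls_n = ls_d = 0
    for _, sess in trials.groupby(["subject_id", "session"], sort=True):
        for prev, nxt in _free_pairs(sess):
            if prev.choice == "large" and not prev.shock:
                ws_d += 1
                ws_n += int(nxt.choice == "large")
            elif prev.choice == "large" and prev.shock:
                ls_d += 1
                ls_n += int(nxt.choice == "small")
    return WinStayLoseShift(
        ws=ws_n / ws_d if ws_d else np.nan,
        ls=ls_n / ls_d if ls_d else np.nan,
        n_win_opportunities=ws_d,
        n_loss_opportunities=ls_d,
    )


def prl_win_stay_lose_shift(trials: pd.DataFrame) -> WinStayLoseShift:
    """Win-stay / lose-shift over reversal-learning trials.

    Win-stay: correct choice followed by a choice of the lever that was
    correct on the predecessor trial, given the predecessor was rewarded.
    Lose-shift: choice of the lever that was incorrect on the predecessor,
    given a nonrewarded correct predecessor.  Omissions break adjacency.
    """
    ws_n = ws_d = ls_n = ls_d = 0
    for _, sess in trials.groupby(["subject_id", "session"], sort=True):
        rows = list(sess.sort_values("trial").itertuples(index=False))
        for prev, nxt in zip(rows, rows[1:]):
            if prev.omitted or nxt.omitted or not prev.correct:
                continue
            stayed = nxt.choice_lever == prev.correct_side
            if prev.reward:
                ws_d += 1
                ws_n += int(stayed)
            else:
                ls_d += 1
                ls_n += int(not stayed)
    return WinStayLoseShift(
        ws=ws_n / ws_d if ws_d else np.nan,
        ls=ls_n / ls_d if ls_d else np.nan,
        n_win_opportunities=ws_d,
        n_loss_opportunities=ls_d,
    )


@dataclass
class ReversalSummary:
    reversals_raw: int
    trials_completed: int
    reversals_corrected: float  # rate per nominal session length
    trials_per_reversal: float  # NaN when no reversals


def reversal_summary(
    trials: pd.DataFrame, reversals: list[int], n_trials_nominal: int = 200
) -> ReversalSummary:
    """Omission-corrected reversal rate for one session.

    The raw count is scaled by ``n_trials_nominal / trials_completed`` so
    sessions with omissions are compared on a common footing.
    """
    completed = int((~trials["omitted"].astype(bool)).sum())
    raw = len(reversals)
    corrected = raw * n_trials_nominal / completed if completed else np.nan
    per = completed / raw if raw else np.nan
    return ReversalSummary(raw, completed, corrected, per)


def forced_latency_block_table(
    trials: pd.DataFrame, extrapolate: bool = True
) -> pd.DataFrame:
    """Mean forced-choice latency per subject x lever x block.

    Omitted trials are excluded from the means.  When a subject omitted every
    forced trial of a lever in a block and ``extrapolate`` is on, the prior
    block's mean is carried forward and the cell flagged ``extrapolated``.  A
    missing first block has no prior block; it stays missing and is flagged
    ``unresolved``.
    """
    forced = trials[(trials["trial_type"] == "forced") & (~trials["omitted"])]
    means = (
        forced.groupby(["subject_id", "choice", "block"])["latency"]
        .mean()
        .rename("latency")
    )
    subjects = trials["subject_id"].unique()
    levers = ["large", "small"]
    blocks = sorted(trials["block"].unique())
    grid = pd.MultiIndex.from_product(
        [subjects, levers, blocks], names=["subject_id", "lever", "block"]
    )
    means.index = means.index.set_names(["subject_id", "lever", "block"])
    out = means.reindex(grid).reset_index()
    out["extrapolated"] = False
    out["unresolved"] = False
    if extrapolate:
        def _fill(g: pd.DataFrame) -> pd.DataFrame:
            g = g.sort_values("block").copy()
            missing = g["latency"].isna()
            g["latency"] = g["latency"].ffill()
            g["extrapolated"] = missing & g["latency"].notna()
            g["unresolved"] = g["latency"].isna()
            return g

        out = (
            out.groupby(["subject_id", "lever"], group_keys=False)[out.columns]
            .apply(_fill)
            .reset_index(drop=True)
        )
    else:
        out["unresolved"] = out["latency"].isna()
    return out


def free_latency_by_lever(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean free-choice latency per subject and lever, collapsed over blocks.

    NaN for a lever the subject never chose on a completed free trial.
    """
    free = trials[(trials["trial_type"] == "free") & (~trials["omitted"])]
    means = free.groupby(["subject_id", "choice"])["latency"].mean().rename("latency")
    grid = pd.MultiIndex.from_product(
        [trials["subject_id"].unique(), ["large", "small"]],
        names=["subject_id", "lever"],
    )
    means.index = means.index.set_names(["subject_id", "lever"])
    return means.reindex(grid).reset_index()


def stability_check(
    block_summaries: pd.DataFrame, alpha: float = 0.05
) -> tuple[bool, pd.DataFrame]:
    """Three-session stability criterion for block-wise risky choice.

    Runs a session x block repeated-measures ANOVA on the arcsine-transformed
    large-lever proportion over exactly three consecutive sessions (with
    Greenhouse-Geisser correction when sphericity is violated); performance is
    stable when neither the session main effect nor the session x block
    interaction is significant.  Subjects with an undefined block proportion
    (every free trial omitted) are dropped from the check.
    """
    df = block_summaries.copy()
    sessions = sorted(df["session"].unique())
    if len(sessions) < 3:
        raise ValueError(f"need 3 consecutive sessions, got {len(sessions)}")
    df = df[df["session"].isin(sessions[-3:])]
    if "p_large_arcsine" not in df.columns:
        df["p_large_arcsine"] = arcsine_transform(df["p_large"].to_numpy())
    ok = (
        df.pivot_table(
            index="subject_id", columns=["session", "block"],
            values="p_large_arcsine",
        )
        .dropna()
        .index
    )
    df = df[df["subject_id"].isin(ok)]
    table = rm_anova_two_way(
        df, dv="p_large_arcsine", within=("session", "block"),
        subject="subject_id", alpha=alpha,
    )
    p_session = float(table.loc[table["effect"] == "session", "p"].iloc[0])
    p_inter = float(table.loc[table["effect"] == "session*block", "p"].iloc[0])
    return bool(p_session > alpha and p_inter > alpha), table


DEFAULT_CROSS_TASK_MEASURES = (
    "risk_score",
    "shock_threshold",
    "mean_reversals",
    "mean_breakpoint",
)


def cross_task_correlations(
    subject_table: pd.DataFrame,
    measures=DEFAULT_CROSS_TASK_MEASURES,
    group_col: str = "age_group",
) -> pd.DataFrame:
    """Spearman rank correlations between task measures, within each group.

    Pairwise-complete: each pair uses the subjects with both measures present.
    A constant column has an undefined rank correlation and yields NaN.
    """
    rows = []
    for group, g in subject_table.groupby(group_col, sort=True):
        if len(g) < 4:
            raise ValueError(f"group {group!r} has {len(g)} subjects; need >= 4")
        for i, ma in enumerate(measures):
            for mb in measures[i + 1 :]:
                sub = g[[ma, mb]].dropna()
                if len(sub) >= 4 and sub[ma].nunique() > 1 and sub[mb].nunique() > 1:
                    rho, p = sps.spearmanr(sub[ma], sub[mb])
                else:
                    rho, p = np.nan, np.nan
                rows.append(
                    {"group": group, "var_a": ma, "var_b": mb,
                     "rho": rho, "p": p, "n": len(sub)}
                )
    return pd.DataFrame(rows)


def risk_scores(
    block_summaries: pd.DataFrame, risk_blocks=(2, 3, 4, 5)
) -> pd.Series:
    """Per-subject risky-choice score: arcsine-transformed large-lever
    proportion averaged over the punishment blocks (2-5) and sessions."""
    df = block_summaries[block_summaries["block"].isin(risk_blocks)]
    return df.groupby("subject_id")["p_large_arcsine"].mean().rename("risk_score")
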