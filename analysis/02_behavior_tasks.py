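#!/usr/bin/env python
"""Run all four behavioral tasks for the default cohort and write the
per-subject summary tables.

Stages: risky decision-making sessions until the three-session stability
criterion passes; the flinch staircase; eight reversal-learning sessions; and
seven progressive-ratio sessions.  Prints the block-wise group means (the
age x block pattern), win-stay/lose-shift, and the group task summaries.
"""

from pathlib import Path

import pandas as pd

import ratrisk as rr
from ratrisk import metrics
from ratrisk.pipeline import (
    RunConfig,
    simulate_pr,
    simulate_prl,
    simulate_rdt_to_stability,
    simulate_staircases,
)

MASTER_SEED = 2026
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = RunConfig(cohort=rr.CohortSpec(20, 18, master_seed=MASTER_SEED))
    agents = rr.make_cohort(config.cohort)
    labels = pd.Series({a.subject_id: a.age_group for a in agents})
    RESULTS.mkdir(exist_ok=True)

    rdt_trials, info = simulate_rdt_to_stability(agents, config)
    print(f"RDT stable after {info['n_sessions']} sessions (stable={info['stable']})")
    summaries = metrics.block_choice_summary(rdt_trials)
    last3 = summaries[summaries["session"] > info["n_sessions"] - 3].copy()
    last3["age_group"] = last3["subject_id"].map(labels)
    last3.to_csv(RESULTS / "rdt_block_summary.csv", index=False)
    block_means = last3.groupby(["age_group", "block"])["p_large"].mean().unstack()
    print("mean P(large, risky lever) by block:")
    print(block_means.round(3).to_string())

    wsls = pd.DataFrame(
        dict(subject_id=s, age_group=labels[s],
             **vars(metrics.rdt_win_stay_lose_shift(g)))
        for s, g in rdt_trials.groupby("subject_id")
    )
    wsls.to_csv(RESULTS / "rdt_ws_ls.csv", index=False)
    print("RDT win-stay / lose-shift group means:")
    print(wsls.groupby("age_group")[["ws", "ls"]].mean().round(3).to_string())

    stair = simulate_staircases(agents, config)
    stair.to_csv(RESULTS / "staircase.csv", index=False)
    print("shock reactivity thresholds (uA):")
    print(stair.groupby("age_group")["shock_threshold"].agg(["mean", "sem"]).round(1).to_string())

    prl_trials, prl_summary = simulate_prl(agents, config)
    prl_summary.to_csv(RESULTS / "prl_summary.csv", index=False)
    print("omission-corrected reversals per session:")
    print(prl_summary.groupby("age_group")["reversals_corrected"].mean().round(2).to_string())

    pr = simulate_pr(agents, config)
    pr.to_csv(RESULTS / "pr_sessions.csv", index=False)
    print("progressive ratio (means across sessions):")
    print(pr.groupby("age_group")[["presses", "rewards", "breakpoint"]].mean().round(1).to_string())

    measures = (
        stair[["subject_id", "age_group", "shock_threshold"]]
        .merge(metrics.risk_scores(last3), on="subject_id")
        .merge(prl_summary.groupby("subject_id")["reversals_corrected"]
               .mean().rename("mean_reversals"), on="subject_id")
        .merge(pr.groupby("subject_id")["breakpoint"]
               .mean().rename("mean_breakpoint"), on="subject_id")
    )
    measures.to_csv(RESULTS / "subject_measures.csv", index=False)
    print(f"wrote per-subject tables to {RESULTS}")


if __name__ == "__main__":
    main()
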