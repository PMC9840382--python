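#!/usr/bin/env python
"""Replicate the study's qualitative headline across independent cohorts.

For 20 master seeds, draws a fresh default cohort and checks the ground-truth
pattern end to end: risky choice declining across the punishment blocks in
both groups, aged below young in the high-risk blocks, and higher mean aged
connectivity z.  Writes the per-seed outcomes to results/headline.json.
"""

import json
from pathlib import Path

from ratrisk.pipeline import headline_pattern

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_SEEDS = 20


def main() -> None:
    outcomes = {}
    for seed in range(1, N_SEEDS + 1):
        h = headline_pattern(seed)
        outcomes[seed] = {k: h[k] for k in
                          ("declining_risky_choice", "aged_below_young_blocks_3_5",
                           "aged_connectivity_above_young", "pass")}
    n_pass = sum(o["pass"] for o in outcomes.values())
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "headline.json").write_text(json.dumps(
        {"n_seeds": N_SEEDS, "n_pass": n_pass, "per_seed": outcomes}, indent=2
    ))
    print(f"headline pattern reproduced in {n_pass}/{N_SEEDS} independent cohorts")
    for seed, o in outcomes.items():
        if not o["pass"]:
            print(f"  seed {seed} failed: {o}")


if __name__ == "__main__":
    main()
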