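#!/usr/bin/env python
"""Draw the default synthetic cohort (20 young, 18 aged) and write the
per-subject manifest of generative parameters.

The printed group means show the built-in ground truth: aged subjects carry a
larger shock-aversion coefficient, higher omission rates, lower
progressive-ratio press rates, and identical learning-rate / inverse
temperature / flinch-threshold distributions.
"""

from pathlib import Path

import ratrisk as rr

MASTER_SEED = 2026
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    spec = rr.CohortSpec(n_young=20, n_aged=18, master_seed=MASTER_SEED)
    agents = rr.make_cohort(spec)
    table = rr.agents_to_frame(agents)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "agents.csv", index=False)

    print(f"cohort: {spec.n_young} young / {spec.n_aged} aged, master seed {MASTER_SEED}")
    means = table.groupby("age_group")[
        ["shock_aversion_kappa", "omission_prob", "rl_alpha", "rl_beta",
         "pr_base_rate", "threshold_mu", "locomotor_rate"]
    ].mean().round(3)
    print(means.to_string())
    print(f"wrote {RESULTS / 'agents.csv'} ({len(table)} subjects)")


if __name__ == "__main__":
    main()
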