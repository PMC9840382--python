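# Methods

This note documents the generative models, the fitted model, every default
parameter (with units and rationale), the numerical choices, and the known
limitations of the `ratrisk` pipeline. Nothing in this document is an
empirical claim about animals; every quantitative statement refers to what
the code computes.

## 1. Synthetic cohort

`ratrisk.cohort.make_cohort` draws one `AgentSpec` per subject. Each field
is an independent Gaussian draw from its group's mean/SD in
`src/ratrisk/defaults.yaml`, clipped to the field's valid range. Subject
seeds are spawned from `numpy.random.SeedSequence([master_seed, i])` and
reduced mod 2³¹, so every downstream stream is reproducible from the master
seed alone and all seeds fit in a signed 32-bit integer.

The default group parameters are **fabricated**. They were chosen, before
any outcome-dependent tuning, so that a default cohort expresses the
qualitative structure the analyses are designed to detect:

| Field | Units | Young (mean, sd) | Aged (mean, sd) | Rationale |
|---|---|---|---|---|
| `shock_aversion_kappa` | utility / unit P(shock) | 1.2, 0.15 | 2.2, 0.30 | The only parameter that differs in the risky-choice policy; produces a decline across blocks in both groups, steeper in aged (expected free-choice P(large) ≈ .92/.85/.73/.56/.38 young vs. ≈ .92/.76/.44/.17/.05 aged). |
| `softmax_beta_rdt` | 1 / utility | 2.5, 0.3 | 2.5, 0.3 | Shared choice stochasticity; no group difference by design. |
| `omission_prob` | per trial | 0.017, 0.010 | 0.086, 0.030 | Aged subjects omit more. |
| `rl_alpha` | — | 0.45, 0.15 | 0.45, 0.15 | No group difference in learning rate by design. |
| `rl_beta` | — | 3.0, 1.0 | 3.0, 1.0 | No group difference in decision noise by design. |
| `pr_base_rate` | presses / min | 30, 8 | 18, 6 | Lower motivation in aged. |
| `pr_giving_up_hazard` | quits / min | 0.10, 0.03 | 0.25, 0.08 | Earlier breakpoints in aged. |
| `threshold_mu` | µA | 150, 20 | 150, 20 | No group difference in shock reactivity by design. |
| `slope_sigma` | µA | 20, 5 | 20, 5 | Psychometric spread of the flinch response. |
| `locomotor_rate` | counts / interval | 9.7, 2.0 | 6.1, 1.5 | Lower activity in aged. |
| `latency_scale` | — | 1.0, 0.15 | 1.5, 0.20 | Slower responding in aged. |

In the reversal-learning simulation, omission probabilities are fixed per
group (young 0.005, aged 0.015 per trial) rather than reusing the RDT
omission parameter, since omission pressure differs between tasks.

### What the generator emulates

- Block-graded avoidance of the punished lever, with the age contrast
  carried entirely by the utility weight on shock probability.
- Discrete-trial operant structure: forced-choice sampling blocks, response
  omissions, lognormal response latencies that lengthen on the risky lever
  as shock probability rises (median 1.0 + 1.5 · P(shock) s, σ = 0.35 on
  the log scale, times the subject's `latency_scale`; the latency model is
  a fabrication — no distributional form was assumed from data).
- Reward-driven trial-by-trial learning in the reversal task via the same
  delta-rule/softmax model that is later fitted (a well-specified case,
  deliberately, so parameter recovery is meaningful).
- Ratio-schedule persistence as a Poisson pressing process with an
  exponential giving-up hazard.
- A psychometric flinch observer: P(flinch at amplitude a) =
  Φ-like logistic in (a − threshold_mu)/slope_sigma.
- Stationary AR(1) ROI time series with a specified cross-ROI correlation
  matrix (young: 0.25 on all 15 pairs of VTA, PrL, NAcSh, lOFC, vOFC, BLA;
  aged: +0.3 Fisher z, i.e. r ≈ 0.505, on the six pairs BLA–lOFC, BLA–vOFC,
  lOFC–NAcSh, lOFC–vOFC, PrL–VTA, VTA–NAcSh). Both matrices are verified
  positive definite (smallest eigenvalues 0.75 and ≈ 0.303).

### What it does not emulate

- No within-session or across-session learning of the RDT contingencies:
  the risky-choice policy is a static utility rule, so "stability" is
  reached almost immediately and satiety/fatigue trends are absent.
- No satiety, circadian, or motivational drift inside sessions.
- No coupling between behavior and connectivity: ROI time series are drawn
  independently of the behavioral parameters, so behavior–connectivity
  correlations are null by construction.
- No estrous, weight, housing, or other covariates; no attrition.
- Shock affects behavior only through the utility weight; there is no
  shock-sensitization or carry-over between trials beyond win-stay/
  lose-shift structure implied by the policy.

## 2. Task engines

### Risky decision task

Five blocks (`RDTConfig`): 8 forced trials (4 per lever, shuffled in pairs
so each consecutive pair contains both levers) then 10 free-choice trials;
shock probabilities (0, 0.25, 0.5, 0.75, 1.0); rewards 2 vs. 1 pellets;
10 s response window. The forced-trial shock schedule is *dependent*: for
each block the 4 forced large-lever trials receive exactly
`round(4 · p)` shocks in shuffled order (a multiset permutation), so the
experienced forced-sampling probabilities match the nominal ones exactly in
every session. Free-choice shocks are i.i.d. Bernoulli(p) draws from a
dedicated stream. Omitted forced trials still consume their scheduled shock
draw so that the schedule stays aligned.

The generative free-choice policy is
P(large) = σ(β_rdt · [(2 − κ·p) − 1]), i.e. a softmax over the fabricated
utilities u(large) = 2 − κ·p and u(safe) = 1.

Sessions repeat (minimum 3, cap 45) until `metrics.stability_check` passes:
a two-within-factor repeated-measures ANOVA (session × block) on
arcsine-transformed free-choice proportions of the last three sessions, with
stability declared when both the session main effect and the session × block
interaction have p > 0.05.

### Probabilistic reversal learning

200 trials; correct lever rewarded with p = 0.8, incorrect with p = 0.2;
after 8 consecutive correct choices the correct side reverses. An omission
or incorrect choice resets the consecutive-correct counter — the protocol
description is ambiguous on omissions, and resetting is the conservative
reading (an omission is not evidence of tracking the contingency); this is
an open design decision, isolated in one place in `run_prl_session`.
Reversal counts are omission-corrected as reversals × 200 / completed
trials.

### Progressive ratio

Press requirement for reward r: N(r) = r(r+1)(r+2)/6. Pressing is a
Poisson process at the subject's `pr_base_rate`; after each reward the
subject quits with an exponential giving-up hazard, and a session ends when
10 minutes (`giving_up_window_min`) pass without completing the next ratio,
or at the 120-minute cap. Breakpoint = the last *completed* ratio
requirement (0 if none).

### Shock-reactivity staircase

Amplitude starts at 50 µA and moves +25 µA after no-flinch, −25 µA after
flinch, never below the 50 µA start (floor rule). The run terminates once
at least 3 flinches have occurred *and* the most recent required descent
has been expressed (the terminating condition in code: ≥ 3 flinches and the
last delivery a non-flinch, or the floor case). Threshold = mean amplitude
of the first three flinches. Boundary cases: an observer that flinches at
every amplitude is floored at 50 µA and assigned threshold 50 µA
(documented edge case); an observer silent up to the 2000 µA safety cap
raises `StaircaseNonTerminatingError` rather than returning a fabricated
threshold.

## 3. Reinforcement-learning model and fitting

Delta rule with per-session zero-initialized values and softmax choice; for
two options the choice probability reduces to a logistic of β·(V⁰ − V¹).
The per-session negative log-likelihood is minimized over α ∈ [0, 1],
β ∈ [0, 50].

Numerical choices, with rationale:

- **β cap at 50.** The likelihood is flat in β once choice is effectively
  deterministic; an unbounded β only adds optimizer pathology. 50 is far
  beyond any behaviorally distinguishable value at these trial counts.
- **Probability floor 10⁻¹² inside the log.** Prevents −∞ at parameter
  corners (e.g. β at bound with a "wrong" choice). Tested not to move the
  optimum on well-posed data.
- **Multi-start strategy.** 16 seeded Latin-hypercube starts (β scaled to
  [0, 10]) refined with L-BFGS-B, plus the top 3 cells of a 51 × 51 coarse
  likelihood grid refined with Nelder–Mead, plus a final Nelder–Mead polish
  of the incumbent. Rationale: the likelihood has flat ridges along α = 0
  and β = 0 where the projected numerical gradient vanishes, so L-BFGS-B
  alone can stall at the (0, 0) corner; the grid + simplex stage recovers
  those cases. With `check_lattice=True` the fit verifies it is not beaten
  by the full coarse lattice.
- **Tie-breaking.** Optima equal within 10⁻⁹ resolve to the lowest (α, β),
  making fits deterministic.
- **Diagnostics.** Sessions with < 20 usable trials are flagged `low_n`;
  sessions with constant choices *and* constant rewards are flagged
  `non_identifiable` (β = 0 makes α meaningless — the documented low-β
  non-identifiable region of parameter recovery).

## 4. Behavioral metrics and statistics

- Choice proportions are arcsine-square-root transformed (asin(√p), in
  radians, `metrics.arcsine_transform`) before ANOVA, the standard
  variance-stabilizing choice for proportions.
- RDT win-stay/lose-shift: a *win* is a free-choice large-lever trial
  without shock, a *loss* one with shock; adjacency is defined over
  consecutive free-choice trials within a session, forced trials are
  transparent, omissions break adjacency. The task description is silent on
  these conventions; they are documented here and unit-tested.
- The two-within-factor repeated-measures ANOVA (`stats.rm_anova_two_way`)
  is implemented from orthonormal contrast matrices, with Mauchly's
  sphericity test and Greenhouse–Geisser correction applied when sphericity
  is rejected at α = 0.05 **or untestable** (too few subjects for the
  contrast dimension, or a degenerate covariance) — the conservative
  fallback. F and p match `statsmodels` AnovaRM exactly and the GG epsilon
  matches `pingouin.epsilon` on collapsed factors (tested).
- Forced-trial latency block tables forward-fill unresolved cells and flag
  extrapolated/unresolved entries rather than silently imputing.

## 5. Connectivity

Per subject, T = 300 timepoints (TR 2.0 s) of AR(1) noise (φ = 0.3,
stationary initialization via `scipy.signal.lfilter`) are mixed through the
symmetric eigendecomposition square root of the group correlation matrix.
Pairwise Pearson r per ROI pair is bootstrapped by resampling *timepoints*
(paired columns, 1000 resamples; an optional block bootstrap is provided
because AR(1) samples are not exchangeable — the default remains the simple
bootstrap for transparency, a documented open decision). Fisher
z = atanh(r) with r clipped to ±(1 − 10⁻¹²); degenerate (constant) series
yield NaN with a flag. Group analysis: pair-wise Bonferroni-corrected
two-sample t contrasts on z, plus a mixed ANOVA (age between × pair within,
`pingouin.mixed_anova`).

## 6. Pipeline and reproducibility

`pipeline.run_full_study` chains all stages; every stage derives its seeds
with `derive_seed(master, label, *indices)` (CRC-32 of the label into
`SeedSequence`, reduced mod 2³¹), so no two stages share a stream and a
master seed reproduces the entire bundle bit-for-bit (tested). Trial logs
round-trip through a fixed CSV schema with a JSON metadata sidecar.
`scripts/acceptance.py` recomputes its three summary quantities from scratch
on each run.

## 7. Open design decisions

- PRL omission handling (counter reset) — see §2.
- Simple vs. block bootstrap default for autocorrelated ROI series — see §5.
- The staircase floor rule at the starting amplitude — see §2.
- The RDT stability criterion uses uncorrected p > 0.05 on both session
  terms; a stricter equivalence-test formulation would be defensible.
- Generative RDT utilities use reward magnitudes directly (2 vs. 1); a
  curvature parameter was deliberately omitted to keep the age contrast in
  a single parameter.

## 8. Limitations

- Defaults are fabricated, not estimated; effect sizes in `results/` are
  properties of the generator, not of any animal population.
- The fitted RL model is the generative model for the reversal task, so
  recovery statistics are upper bounds on what misspecified real data
  would allow.
- Behavior and connectivity are independent by construction; the
  behavior–connectivity correlation stage demonstrates calibration (chance
  level), not a positive result.
- The ANOVA machinery assumes complete, balanced within-subject tables;
  subjects with missing cells are dropped, not imputed.
- Bootstrap CIs on r use the percentile method; no BCa correction.
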