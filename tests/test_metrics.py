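"""Derived behavioral statistics: arcsine transform, win-stay/lose-shift,
reversal summaries, latency tables, stability criterion, rank correlations."""

import numpy as np
import pandas as pd
import pytest

from ratrisk import metrics
from ratrisk.metrics import (
    arcsine_transform,
    block_choice_summary,
    cross_task_correlations,
    forced_latency_block_table,
    free_latency_by_lever,
    prl_win_stay_lose_shift,
    rdt_win_stay_lose_shift,
    reversal_summary,
    stability_check,
)
from ratrisk.stats import rm_anova_two_way


def rdt_free_trials(seq, subject="s1", session=1):
    """Build free-choice RDT rows from (choice, shock, omitted) tuples."""
    rows = []
    for t, (choice, shock, omitted) in enumerate(seq, start=1):
        rows.append(
            {
                "task": "RDT", "subject_id": subject, "session": session,
                "block": 1 + (t - 1) // 10, "trial": t, "trial_type": "free",
                "lever_offered": "both",
                "choice": "none" if omitted else choice,
                "reward": 0 if omitted else (2 if choice == "large" else 1),
                "shock": bool(shock) and not omitted, "omitted": bool(omitted),
                "latency": np.nan if omitted else 1.0,
            }
        )
    return pd.DataFrame(rows)


class TestArcsine:
    @pytest.mark.parametrize(
        "p, expected", [(0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4)]
    )
    def test_closed_form(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_strictly_monotone_on_grid(self):
        grid = np.linspace(0, 1, 1001)
        out = arcsine_transform(grid)
        assert np.all(np.diff(out) > 0)

    def test_domain_error(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                arcsine_transform(bad)


class TestRDTWinStayLoseShift:
    def test_perfect_stay(self):
        seq = [("large", False, False)] * 11
        res = rdt_win_stay_lose_shift(rdt_free_trials(seq))
        assert res.ws == 1.0
        assert res.n_win_opportunities == 10
        assert np.isnan(res.ls)  # no shocked trials, no loss opportunities

    def test_never_shifts_after_shock(self):
        seq = [("large", True, False)] * 11
        res = rdt_win_stay_lose_shift(rdt_free_trials(seq))
        assert res.ls == 0.0
        assert res.n_loss_opportunities == 10

    def test_hand_built_twelve_trial_sequence(self):
        # 5 win opportunities with 3 stays; 2 loss opportunities with 1 shift
        # (the trailing shocked trial precedes an omission, breaking adjacency)
        seq = [
            ("large", False, False),  # win -> stays
            ("large", False, False),  # win -> stays
            ("large", False, False),  # win -> shifts
            ("small", False, False),
            ("large", True, False),   # loss -> shifts
            ("small", False, False),
            ("large", False, False),  # win -> shifts
            ("small", False, False),
            ("large", False, False),  # win -> stays
            ("large", True, False),   # loss -> stays
            ("large", True, False),   # followed by omission: not counted
            ("large", False, True),
        ]
        res = rdt_win_stay_lose_shift(rdt_free_trials(seq))
        assert (res.ws, res.ls) == (0.6, 0.5)
        assert (res.n_win_opportunities, res.n_loss_opportunities) == (5, 2)

    def test_opportunities_partition_eligible_pairs(self):
        # conservation: every adjacent non-omitted free pair is a win
        # opportunity, a loss opportunity, or a small-lever predecessor
        rng = np.random.default_rng(4)
        seq = [
            (rng.choice(["large", "small"]), bool(rng.random() < 0.3),
             bool(rng.random() < 0.1))
            for _ in range(200)
        ]
        seq = [(c, s and c == "large", o) for c, s, o in seq]
        df = rdt_free_trials(seq)
        res = rdt_win_stay_lose_shift(df)
        pairs = [
            (a, b)
            for a, b in zip(seq, seq[1:])
            if not a[2] and not b[2]
        ]
        small_pred = sum(1 for a, _ in pairs if a[0] == "small")
        assert res.n_win_opportunities + res.n_loss_opportunities + small_pred == len(pairs)

    def test_adjacency_does_not_cross_sessions(self):
        one = rdt_free_trials([("large", False, False)] * 2, session=1)
        two = rdt_free_trials([("large", False, False)] * 2, session=2)
        res = rdt_win_stay_lose_shift(pd.concat([one, two], ignore_index=True))
        assert res.n_win_opportunities == 2  # one pair per session


def prl_trials(rows, subject="s1", session=1):
    out = []
    for t, (lever, correct_side, reward, omitted) in enumerate(rows, start=1):
        out.append(
            {
                "task": "PRL", "subject_id": subject, "session": session,
                "trial": t, "choice_lever": "none" if omitted else lever,
                "correct_side": correct_side,
                "correct": (lever == correct_side) and not omitted,
                "reward": 0 if omitted else reward, "omitted": bool(omitted),
                "latency": np.nan if omitted else 1.0,
            }
        )
    return pd.DataFrame(out)


class TestPRLWinStayLoseShift:
    def test_always_correct_always_rewarded(self):
        rows = [("left", "left", 1, False)] * 10
        res = prl_win_stay_lose_shift(prl_trials(rows))
        assert res.ws == 1.0
        assert np.isnan(res.ls)

    def test_shift_after_every_nonreward(self):
        # correct unrewarded choices each followed by the other lever
        rows = [
            ("left", "left", 0, False),
            ("right", "left", 0, False),
            ("left", "left", 0, False),
            ("right", "left", 0, False),
        ]
        res = prl_win_stay_lose_shift(prl_trials(rows))
        assert res.ls == 1.0

    def test_twenty_trial_sequence_matches_enumeration(self):
        rng = np.random.default_rng(11)
        rows = []
        correct = "left"
        for t in range(20):
            if t == 10:
                correct = "right"  # one reversal mid-sequence
            lever = rng.choice(["left", "right"])
            reward = int(rng.random() < (0.8 if lever == correct else 0.2))
            rows.append((lever, correct, reward, False))
        res = prl_win_stay_lose_shift(prl_trials(rows))
        ws_n = ws_d = ls_n = ls_d = 0
        for (lv, cs, rw, _), (lv2, _, _, _) in zip(rows, rows[1:]):
            if lv != cs:
                continue
            stayed = lv2 == cs
            if rw:
                ws_d += 1
                ws_n += stayed
            else:
                ls_d += 1
                ls_n += not stayed
        assert res.n_win_opportunities == ws_d
        assert res.n_loss_opportunities == ls_d
        if ws_d:
            assert res.ws == pytest.approx(ws_n / ws_d)
        if ls_d:
            assert res.ls == pytest.approx(ls_n / ls_d)


class TestReversalSummary:
    def test_no_omission_identity(self):
        df = prl_trials([("left", "left", 1, False)] * 200)
        s = reversal_summary(df, list(range(10)))
        assert s.reversals_corrected == 10.0
        assert s.trials_per_reversal == 20.0

    def test_omission_correction(self):
        rows = [("left", "left", 1, False)] * 180 + [("left", "left", 0, True)] * 20
        s = reversal_summary(prl_trials(rows), list(range(10)))
        assert s.reversals_corrected == pytest.approx(10 * 200 / 180)

    def test_zero_reversals(self):
        df = prl_trials([("left", "right", 0, False)] * 200)
        s = reversal_summary(df, [])
        assert s.reversals_corrected == 0.0
        assert np.isnan(s.trials_per_reversal)

    def test_correction_increases_with_omissions(self):
        base = [("left", "left", 1, False)] * 200
        vals = []
        for n_omit in (0, 10, 40):
            rows = base[: 200 - n_omit] + [("left", "left", 0, True)] * n_omit
            vals.append(reversal_summary(prl_trials(rows), list(range(5))).reversals_corrected)
        assert vals[0] < vals[1] < vals[2]


def forced_rows(subject, lever, block, latencies, omitted=False):
    return [
        {
            "task": "RDT", "subject_id": subject, "session": 1, "block": block,
            "trial": 0, "trial_type": "forced", "lever_offered": lever,
            "choice": "none" if omitted else lever,
            "reward": 0 if omitted else 1, "shock": False, "omitted": omitted,
            "latency": np.nan if omitted else lat,
        }
        for lat in latencies
    ]


class TestLatencyTables:
    def test_plain_groupby_when_no_omissions(self):
        rows = (
            forced_rows("s1", "large", 1, [1.0, 2.0])
            + forced_rows("s1", "small", 1, [3.0])
            + forced_rows("s1", "large", 2, [4.0])
            + forced_rows("s1", "small", 2, [5.0])
        )
        out = forced_latency_block_table(pd.DataFrame(rows))
        cell = out[(out["lever"] == "large") & (out["block"] == 1)]["latency"]
        assert cell.iloc[0] == pytest.approx(1.5)
        assert not out["extrapolated"].any()

    def test_prior_block_extrapolation(self):
        rows = (
            forced_rows("s1", "large", 1, [1.0])
            + forced_rows("s1", "large", 2, [np.nan], omitted=True)
            + forced_rows("s1", "large", 3, [2.1])
            + forced_rows("s1", "large", 4, [np.nan], omitted=True)
            + forced_rows("s1", "small", 1, [0.5])
            + forced_rows("s1", "small", 2, [0.5])
            + forced_rows("s1", "small", 3, [0.5])
            + forced_rows("s1", "small", 4, [0.5])
        )
        out = forced_latency_block_table(pd.DataFrame(rows))
        large = out[out["lever"] == "large"].set_index("block")
        assert large.loc[2, "latency"] == pytest.approx(1.0)  # carried from block 1
        assert large.loc[4, "latency"] == pytest.approx(2.1)  # carried from block 3
        assert bool(large.loc[4, "extrapolated"])
        assert not bool(large.loc[3, "extrapolated"])

    def test_block_one_missing_stays_unresolved(self):
        rows = (
            forced_rows("s1", "large", 1, [np.nan], omitted=True)
            + forced_rows("s1", "large", 2, [2.0])
            + forced_rows("s1", "small", 1, [0.5])
            + forced_rows("s1", "small", 2, [0.5])
        )
        out = forced_latency_block_table(pd.DataFrame(rows))
        b1 = out[(out["lever"] == "large") & (out["block"] == 1)].iloc[0]
        assert np.isnan(b1["latency"])
        assert bool(b1["unresolved"])

    def test_simulated_subjects_have_no_flagged_cells(self, make_agent):
        from ratrisk.tasks import RDTConfig, run_rdt_session

        logs = [
            run_rdt_session(make_agent(subject_id=f"s{i}", seed=i), RDTConfig(), i)
            for i in range(30)
        ]
        out = forced_latency_block_table(pd.concat(logs, ignore_index=True))
        assert not out["extrapolated"].any()
        assert not out["unresolved"].any()

    def test_free_latency_missing_for_never_chosen_lever(self):
        df = rdt_free_trials([("large", False, False)] * 5)
        out = free_latency_by_lever(df).set_index("lever")
        assert out.loc["large", "latency"] == pytest.approx(1.0)
        assert np.isnan(out.loc["small", "latency"])


def block_summary_frame(values):
    """values[s][session][block] -> long summary table (p_large in [0,1])."""
    rows = []
    for subj, sessions in values.items():
        for session, blocks in sessions.items():
            for block, p in blocks.items():
                rows.append(
                    {"subject_id": subj, "session": session, "block": block,
                     "p_large": p, "n_free": 10, "n_large": int(round(10 * p)),
                     "p_large_arcsine": metrics.arcsine_transform(p)}
                )
    return pd.DataFrame(rows)


class TestStability:
    def test_identical_sessions_are_stable(self):
        base = {1: 0.9, 2: 0.8, 3: 0.6, 4: 0.4, 5: 0.2}
        vals = {
            f"s{i}": {s: {b: min(1, base[b] + 0.02 * i) for b in base} for s in (1, 2, 3)}
            for i in range(8)
        }
        stable, table = stability_check(block_summary_frame(vals))
        assert stable
        assert set(table["effect"]) == {"session", "block", "session*block"}

    def test_drifting_cohort_detected_unstable(self):
        rng = np.random.default_rng(0)
        detected = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals = {
                f"s{i}": {
                    s: {b: float(np.clip(0.7 - 0.1 * b + 0.15 * s + r.normal(0, 0.03), 0, 1))
                        for b in range(1, 6)}
                    for s in (1, 2, 3)
                }
                for i in range(20)
            }
            stable, _ = stability_check(block_summary_frame(vals))
            detected += not stable
        assert detected >= 9

    def test_requires_three_sessions(self):
        vals = {"s1": {1: {1: 0.5}, 2: {1: 0.5}}}
        with pytest.raises(ValueError):
            stability_check(block_summary_frame(vals))

    def test_null_calibration_of_session_effect(self):
        # with exchangeable sessions the session-effect p-value is calibrated:
        # rejection rate ~ alpha (binomial tolerance around 0.05)
        rejections = 0
        n_sims = 300
        for seed in range(n_sims):
            r = np.random.default_rng(10_000 + seed)
            vals = {
                f"s{i}": {
                    s: {b: float(np.clip(0.7 - 0.1 * b + r.normal(0, 0.05), 0, 1))
                        for b in range(1, 6)}
                    for s in (1, 2, 3)
                }
                for i in range(12)
            }
            _, table = stability_check(block_summary_frame(vals))
            p = float(table.loc[table["effect"] == "session", "p"].iloc[0])
            rejections += p <= 0.05
        rate = rejections / n_sims
        assert rate < 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / n_sims)


class TestRmAnovaTwoWay:
    def test_matches_statsmodels_f_values(self, rng):
        from statsmodels.stats.anova import AnovaRM

        rows = []
        Y = rng.normal(size=(10, 3, 4)) + rng.normal(size=(10, 1, 1))
        for s in range(10):
            for i in range(3):
                for j in range(4):
                    rows.append({"subject": f"s{s}", "A": f"a{i}", "B": f"b{j}",
                                 "y": Y[s, i, j]})
        df = pd.DataFrame(rows)
        mine = rm_anova_two_way(df, "y", ("A", "B"), "subject").set_index("effect")
        ref = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        assert mine.loc["A", "F"] == pytest.approx(ref.loc["A", "F Value"])
        assert mine.loc["B", "F"] == pytest.approx(ref.loc["B", "F Value"])
        assert mine.loc["A*B", "F"] == pytest.approx(ref.loc["A:B", "F Value"])
        assert mine.loc["A", "p_uncorrected"] == pytest.approx(ref.loc["A", "Pr > F"])

    def test_gg_epsilon_matches_pingouin_on_collapsed_factor(self, rng):
        import pingouin as pg

        Y = rng.normal(size=(12, 3, 5))
        rows = [
            {"subject": f"s{s}", "A": f"a{i}", "B": f"b{j}", "y": Y[s, i, j]}
            for s in range(12) for i in range(3) for j in range(5)
        ]
        df = pd.DataFrame(rows)
        mine = rm_anova_two_way(df, "y", ("A", "B"), "subject").set_index("effect")
        collapsed = df.groupby(["subject", "A"])["y"].mean().reset_index()
        wide = collapsed.pivot(index="subject", columns="A", values="y")
        assert mine.loc["A", "eps_gg"] == pytest.approx(
            pg.epsilon(wide, correction="gg"), abs=1e-9
        )


class TestCrossTaskCorrelations:
    def table(self, risk, thresh, rev, bp, group="young"):
        return pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(len(risk))],
             "age_group": group, "risk_score": risk, "shock_threshold": thresh,
             "mean_reversals": rev, "mean_breakpoint": bp}
        )

    def test_monotone_pairs(self):
        t = self.table([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [10, 8, 6, 4, 2],
                       [1, 1, 1, 1, 1])
        out = cross_task_correlations(t).set_index(["var_a", "var_b"])
        assert out.loc[("risk_score", "shock_threshold"), "rho"] == pytest.approx(1.0)
        assert out.loc[("risk_score", "mean_reversals"), "rho"] == pytest.approx(-1.0)
        assert np.isnan(out.loc[("risk_score", "mean_breakpoint"), "rho"])

    def test_hand_table_matches_rank_computation(self):
        from scipy import stats as sps

        risk = [0.3, 0.9, 0.1, 0.7, 0.5, 0.8]
        rev = [4, 9, 2, 5, 8, 1]
        t = self.table(risk, [1, 2, 3, 4, 5, 6], rev, [7, 1, 3, 9, 2, 5])
        out = cross_task_correlations(t).set_index(["var_a", "var_b"])
        rho, p = sps.spearmanr(risk, rev)
        assert out.loc[("risk_score", "mean_reversals"), "rho"] == pytest.approx(rho)
        assert out.loc[("risk_score", "mean_reversals"), "p"] == pytest.approx(p)

    def test_small_group_rejected(self):
        t = self.table([1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            cross_task_correlations(t)


class TestBlockChoiceSummary:
    def test_counts_and_proportion(self, make_agent):
        from ratrisk.tasks import RDTConfig, run_rdt_session

        df = run_rdt_session(make_agent(), RDTConfig(), 5)
        out = block_choice_summary(df)
        assert len(out) == 5
        assert (out["n_free"] == 10).all()
        free = df[(df["trial_type"] == "free") & (~df["omitted"])]
        by_hand = free.groupby("block")["choice"].apply(lambda c: (c == "large").mean())
        assert np.allclose(out.sort_values("block")["p_large"], by_hand.sort_index())

    def test_fully_omitted_block_yields_nan(self, make_agent):
        from ratrisk.tasks import RDTConfig, run_rdt_session

        ghost = make_agent(omission_prob=0.99999999)
        out = block_choice_summary(run_rdt_session(ghost, RDTConfig(), 5))
        assert out["p_large"].isna().all()
        assert (out["n_free"] == 0).all()
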