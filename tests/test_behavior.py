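"""Lick scoring, blockwise ΔR, cumulative curves, condition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trials
from vnspupil import (
    LickEvents,
    block_delta_r,
    condition_summary,
    cumulative_response_curve,
    delta_r_density,
    score_trials,
)


def naive_score(trials, lick_times):
    """Brute-force O(n*m) interval check (independent oracle)."""
    out = []
    for _, row in trials.iterrows():
        lo = row["sound_onset"] + 0.2
        hi = row["sound_offset"] + 0.15
        out.append(any(lo <= lk < hi for lk in lick_times))
    return np.array(out)


class TestScoreTrials:
    def test_lick_inside_window_responds(self):
        trials = make_trials([10.0])
        resp = score_trials(trials, LickEvents(np.array([10.5])))
        assert resp["responded"].iloc[0]

    def test_lick_before_window_does_not_respond(self):
        """A lick 0.1 s after onset precedes the 0.2-s anticipatory window."""
        trials = make_trials([10.0])
        resp = score_trials(trials, LickEvents(np.array([10.1])))
        assert not resp["responded"].iloc[0]

    def test_empty_licks_all_false(self):
        resp = score_trials(make_trials([1.0, 5.0]), LickEvents())
        assert not resp["responded"].any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        trials = make_trials(np.sort(rng.uniform(0, 200, n)) + np.arange(n) * 2.0)
        licks = np.sort(rng.uniform(0, 260, int(rng.integers(0, 80))))
        got = score_trials(trials, LickEvents(licks))["responded"].to_numpy()
        np.testing.assert_array_equal(got, naive_score(trials, licks))


def responses_frame(labels, responded):
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(labels)),
            "sound_label": labels,
            "responded": responded,
            "day": 1,
            "vns_condition": "paired",
            "block_id": 0,
        }
    )


class TestBlockDeltaR:
    def test_maximal_preference(self):
        labels = ["T1", "T2"] * 10
        resp = responses_frame(labels, [lab == "T1" for lab in labels])
        blocks = block_delta_r(resp)
        assert len(blocks) == 1
        assert blocks["delta_r"].iloc[0] == pytest.approx(1.0)

    def test_equal_rates_give_zero(self):
        labels = ["T1", "T2"] * 10
        resp = responses_frame(labels, [True] * 20)
        assert block_delta_r(resp)["delta_r"].iloc[0] == pytest.approx(0.0)

    def test_direct_count_example(self):
        """7/10 T1 and 3/10 T2 responses in one block: ΔR = 0.4."""
        labels = ["T1", "T2"] * 10
        responded = []
        t1_seen = t2_seen = 0
        for lab in labels:
            if lab == "T1":
                responded.append(t1_seen < 7)
                t1_seen += 1
            else:
                responded.append(t2_seen < 3)
                t2_seen += 1
        blocks = block_delta_r(responses_frame(labels, responded))
        assert blocks["delta_r"].iloc[0] == pytest.approx(0.4)
        assert blocks["n_t1"].iloc[0] == 10 and blocks["n_t2"].iloc[0] == 10

    def test_partial_block_rule(self):
        # 26 trials: final block of 6 (3 T1 + 3 T2) is kept; 25 would drop it
        labels = ["T1", "T2"] * 13
        blocks = block_delta_r(responses_frame(labels, [True] * 26))
        assert len(blocks) == 2
        labels = ["T1", "T2"] * 12 + ["T1"]
        blocks = block_delta_r(responses_frame(labels, [True] * 25))
        assert len(blocks) == 1

    def test_block_missing_one_type_flagged(self):
        labels = ["T1"] * 20 + ["T1", "T2"] * 10
        blocks = block_delta_r(responses_frame(labels, [True] * 40))
        assert blocks["flagged"].iloc[0]
        assert np.isnan(blocks["delta_r"].iloc[0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_antisymmetric(self, seed):
        """ΔR lies in [-1, 1] and flips sign when T1/T2 labels are swapped."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        labels = rng.choice(["T1", "T2"], size=n).tolist()
        responded = rng.random(n) < 0.5
        resp = responses_frame(labels, responded)
        blocks = block_delta_r(resp)
        vals = blocks["delta_r"].dropna()
        assert ((vals >= -1) & (vals <= 1)).all()
        swapped = resp.copy()
        swapped["sound_label"] = swapped["sound_label"].map({"T1": "T2", "T2": "T1"})
        flipped = block_delta_r(swapped)["delta_r"]
        np.testing.assert_allclose(flipped.to_numpy(), -blocks["delta_r"].to_numpy())

    def test_ref_trials_never_affect_delta_r(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["T1", "T2"], size=40).tolist()
        resp = responses_frame(labels, rng.random(40) < 0.6)
        base = block_delta_r(resp)["delta_r"].to_numpy()
        # interleave REF trials with arbitrary responses
        ref = responses_frame(["REF"] * 15, rng.random(15) < 0.5)
        ref["trial_id"] = ref["trial_id"] * 3 + 100
        mixed = pd.concat([resp, ref]).sort_values("trial_id")
        np.testing.assert_allclose(block_delta_r(mixed)["delta_r"].to_numpy(), base)


class TestCumulativeCurve:
    def test_no_licks_flat_zero(self):
        trials = make_trials([10.0, 20.0], label=["T1", "T1"])
        curve = cumulative_response_curve(trials, LickEvents(), labels=("T1",))
        assert (curve["T1"] == 0).all()

    def test_step_at_common_latency(self):
        onsets = np.array([10.0, 20.0, 30.0])
        trials = make_trials(onsets)
        curve = cumulative_response_curve(trials, LickEvents(onsets + 0.3), labels=("T1",))
        assert (curve.loc[curve["time"] < 0.295, "T1"] == 0).all()
        assert (curve.loc[curve["time"] > 0.305, "T1"] == 1).all()

    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_bruteforce_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        onsets = np.arange(12) * 5.0 + 3.0
        trials = make_trials(onsets)
        licks = np.sort(rng.uniform(0, 70, 60))
        curve = cumulative_response_curve(trials, LickEvents(licks), labels=("T1",))
        for _, row in curve.iloc[::17].iterrows():
            t = row["time"]
            frac = np.mean([np.any((licks >= o) & (licks <= o + t)) for o in onsets])
            assert row["T1"] == pytest.approx(frac)
        assert (np.diff(curve["T1"]) >= 0).all()
        assert curve["T1"].between(0, 1).all()


class TestSummaries:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        blocks = pd.DataFrame({"delta_r": rng.normal(0.2, 0.3, 200).clip(-1, 1)})
        grid, dens = delta_r_density(blocks)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_all_zero_blocks_give_zero_t(self):
        blocks = pd.DataFrame(
            {"day": 1, "vns_condition": "paired", "difficulty": "no_switch", "delta_r": np.zeros(10)}
        )
        summary, _ = condition_summary(blocks)
        assert summary["mean_delta_r"].iloc[0] == 0.0
        assert summary["t_vs_zero"].iloc[0] == 0.0

    def test_one_sample_power_at_generative_effect(self):
        """Mean ΔR = 0.3, sd 0.2, 30 blocks: the t test nearly always rejects."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 100
        for _ in range(reps):
            blocks = pd.DataFrame(
                {"day": 2, "vns_condition": "paired", "delta_r": rng.normal(0.3, 0.2, 30)}
            )
            s, _ = condition_summary(blocks)
            hits += s["p_vs_zero"].iloc[0] < 0.05
        assert hits / reps >= 0.95

    def test_between_condition_null_p_uniform(self):
        """Identical paired/unpaired distributions: p is uniform on [0, 1]."""
        from scipy import stats

        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            blocks = pd.DataFrame(
                {
                    "day": 2,
                    "vns_condition": ["paired"] * 15 + ["unpaired"] * 15,
                    "delta_r": rng.normal(0.1, 0.25, 30),
                }
            )
            _, contrasts = condition_summary(blocks)
            ps.append(contrasts["p_paired_vs_unpaired"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.04)

    def test_small_cells_omitted(self):
        blocks = pd.DataFrame({"day": [1], "vns_condition": ["paired"], "delta_r": [0.2]})
        summary, _ = condition_summary(blocks)
        assert len(summary) == 0
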