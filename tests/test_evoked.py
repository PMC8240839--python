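"""PSTH computation, epoch responses, and the pre/post rank-sum endpoint."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import make_trials
from vnspupil import (
    BinnedUnitSession,
    GeneratorConfig,
    ValidationError,
    compare_pre_post,
    compute_psth,
    epoch_responses,
    has_sustained_response,
    population_summary,
    ranksum_p,
    simulate_session,
)


def make_binned(rate, time=None, bin_width=0.02, unit="u0", phase="pre"):
    rate = np.atleast_2d(np.asarray(rate, dtype=float))
    n, b = rate.shape
    if time is None:
        time = -0.5 + (np.arange(b) + 0.5) * bin_width
    return BinnedUnitSession(
        unit_id=unit,
        phase=phase,
        bin_width=bin_width,
        time=np.asarray(time),
        rate=rate,
        pupil=np.full_like(rate, 60.0),
        trial_index=np.arange(n),
        trial_id=np.arange(n),
        window=(float(time[0] - bin_width / 2), float(time[-1] + bin_width / 2)),
    )


class TestPSTH:
    def test_deterministic_train_gives_bin_rate(self):
        """One spike per 20 ms bin binned at 50 Hz reads out exactly 50 spk/s."""
        sess = make_binned(np.full((3, 100), 50.0))
        trials = make_trials([0.0, 1.0, 2.0])
        psth = compute_psth(sess, trials)
        np.testing.assert_allclose(psth.mean_rate, 50.0)
        np.testing.assert_allclose(psth.evoked_rate, 0.0)

    def test_homogeneous_poisson_has_no_evoked_response(self):
        rng = np.random.default_rng(0)
        n_trials, n_bins, w = 200, 100, 0.02
        counts = rng.poisson(10.0 * w, size=(n_trials, n_bins))
        sess = make_binned(counts / w)
        trials = make_trials(np.arange(n_trials) * 3.0)
        psth = compute_psth(sess, trials)
        se = np.sqrt(10.0 / w / n_trials)  # per-bin SE of the mean rate
        assert np.abs(psth.evoked_rate.mean()) < 3 * se

    def test_generator_template_recovered(self):
        cfg = GeneratorConfig(seed=3, n_units=1, unit_amp_jitter=0.0)
        trials, units, pupil, _, truth = simulate_session(cfg)
        sess = truth.expected_binned("u000", "pre", trials, deterministic_pupil=True)
        psth = compute_psth(sess, trials, "BF")
        np.testing.assert_allclose(psth.mean_rate, truth.template("u000", sess.time, "pre"), atol=1e-9)

    def test_no_matching_trials_errors(self):
        sess = make_binned(np.zeros((2, 100)))
        with pytest.raises(ValidationError):
            compute_psth(sess, make_trials([0.0, 1.0]), "OFFBF")


class TestEpochs:
    def test_flat_rate_gives_zero_epochs(self):
        sess = make_binned(np.full((4, 100), 7.0))
        ep = epoch_responses(sess, make_trials(np.arange(4) * 3.0))
        np.testing.assert_allclose(ep.onset, 0.0)
        np.testing.assert_allclose(ep.sustained, 0.0)
        np.testing.assert_allclose(ep.offset, 0.0)

    def test_sustained_only_bump(self):
        time = -0.5 + (np.arange(100) + 0.5) * 0.02
        rate = np.full((3, 100), 5.0)
        rate[:, (time > 0.06) & (time < 1.0)] += 12.0
        ep = epoch_responses(make_binned(rate), make_trials(np.arange(3) * 3.0))
        np.testing.assert_allclose(ep.sustained, 12.0)
        np.testing.assert_allclose(ep.onset, 0.0)
        np.testing.assert_allclose(ep.offset, 0.0)

    def test_baseline_shift_invariance(self):
        rng = np.random.default_rng(1)
        rate = rng.poisson(8, size=(10, 100)) / 0.02
        trials = make_trials(np.arange(10) * 3.0)
        a = epoch_responses(make_binned(rate), trials)
        b = epoch_responses(make_binned(rate + 37.0), trials)
        np.testing.assert_allclose(a.sustained, b.sustained, atol=1e-9)
        np.testing.assert_allclose(a.onset, b.onset, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_window_means(self, seed):
        rng = np.random.default_rng(seed)
        rate = rng.gamma(2.0, 5.0, size=(8, 100))
        time = -0.5 + (np.arange(100) + 0.5) * 0.02
        ep = epoch_responses(make_binned(rate), make_trials(np.arange(8) * 3.0))
        for i in range(8):
            spont = rate[i, (time > -0.5) & (time < 0.0)].mean()
            sust = rate[i, (time > 0.06) & (time < 1.0)].mean() - spont
            ons = rate[i, (time > 0.0) & (time < 0.06)].mean() - spont
            off = rate[i, (time > 1.0) & (time < 1.1)].mean() - spont
            assert ep.sustained[i] == pytest.approx(sust)
            assert ep.onset[i] == pytest.approx(ons)
            assert ep.offset[i] == pytest.approx(off)

    def test_epoch_outside_window_errors(self):
        sess = make_binned(np.zeros((2, 100)))
        with pytest.raises(ValidationError):
            epoch_responses(sess, make_trials([0.0, 3.0]), epochs={"sustained": (0.06, 3.0)})


def enum_ranksum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration (independent oracle)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum()
    sums = np.array([ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n)])
    lo = np.mean(sums <= obs)
    hi = np.mean(sums >= obs)
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    @pytest.mark.parametrize("n,m", [(3, 3), (4, 6), (5, 5), (8, 8), (2, 8)])
    def test_matches_exact_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=m)
            assert ranksum_p(x, y) == pytest.approx(enum_ranksum_p(x, y), abs=1e-12)

    def test_identical_constant_samples_give_one(self):
        assert ranksum_p(np.full(6, 2.0), np.full(7, 2.0)) == 1.0


def epochs_from(sess, trials):
    return epoch_responses(sess, trials)


class TestComparePrePost:
    def _random_epochs(self, seed, n=20, shift=0.0, w=0.02):
        """Poisson trials: 10 spk/s spontaneous plus ``shift`` in the sustained epoch."""
        rng = np.random.default_rng(seed)
        time = -0.5 + (np.arange(100) + 0.5) * w
        lam = np.full(100, 10.0)
        lam[(time > 0.06) & (time < 1.0)] += shift
        rate = rng.poisson(lam * w, size=(n, 100)) / w
        return epoch_responses(make_binned(rate), make_trials(np.arange(n) * 3.0))

    def test_same_trials_not_significant(self):
        ep = self._random_epochs(0)
        res = compare_pre_post(ep, ep)
        assert res.diff == 0.0
        assert res.p_unit > 0.99
        assert not res.significant

    def test_antisymmetric_under_phase_swap(self):
        a, b = self._random_epochs(1), self._random_epochs(2, shift=5.0)
        fwd = compare_pre_post(a, b)
        rev = compare_pre_post(b, a)
        assert fwd.diff == pytest.approx(-rev.diff)
        assert fwd.p_unit == pytest.approx(rev.p_unit)

    def test_bonferroni_correction_scales_p(self):
        a, b = self._random_epochs(3), self._random_epochs(4, shift=3.0)
        raw = compare_pre_post(a, b, correction="none")
        corr = compare_pre_post(a, b, correction="bonferroni", n_comparisons=2)
        assert corr.p_unit == pytest.approx(min(1.0, 2 * raw.p_unit))

    def test_minimum_trial_count_enforced(self):
        small = self._random_epochs(5, n=4)
        with pytest.raises(ValidationError):
            compare_pre_post(small, small)

    def test_detects_injected_suppression(self):
        """A 30% sustained suppression with 20+20 trials is mostly detected
        with the correct (negative) sign."""
        hits = signs = 0
        reps = 40
        for seed in range(reps):
            pre = self._random_epochs(seed * 2, shift=20.0)
            post = self._random_epochs(seed * 2 + 1, shift=14.0)  # 30% down
            res = compare_pre_post(pre, post)
            if res.significant:
                hits += 1
                signs += res.diff < 0
        assert hits / reps > 0.5
        assert signs / hits >= 0.9


class TestPopulation:
    def test_exclusion_rule(self):
        quiet = self._flat_epochs(0.2)
        loud = self._flat_epochs(8.0)
        assert not has_sustained_response([quiet])
        assert has_sustained_response([quiet, loud])

    @staticmethod
    def _flat_epochs(amp):
        time = -0.5 + (np.arange(100) + 0.5) * 0.02
        rate = np.full((6, 100), 5.0)
        rate[:, (time > 0.06) & (time < 1.0)] += amp
        return epoch_responses(make_binned(rate), make_trials(np.arange(6) * 3.0))

    def test_population_summary_counts(self):
        pre = TestComparePrePost()._random_epochs(0, shift=20.0)
        post = TestComparePrePost()._random_epochs(1, shift=10.0)
        res = [compare_pre_post(pre, post) for _ in range(3)]
        out = population_summary(res)
        assert out["n_units"] == 3
        assert 0 <= out["fraction_significant"] <= 1
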