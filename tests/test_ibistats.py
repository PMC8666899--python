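"""IBI summaries, sign-flip permutation test and Hochberg correction."""

import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from ibikit import (
    IBISeries,
    compare_summaries,
    hochberg_correct,
    ibi_summary,
    paired_permutation_test,
)
from ibikit.ibistats import EPOCH_METRICS, IBISummary, epoch_summary


def _series(durations, valid=None):
    durations = np.asarray(durations, dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    valid = np.ones(durations.size, bool) if valid is None else np.asarray(valid)
    return IBISeries(starts, starts + durations, valid)


class TestIbiSummary:
    def test_uniform_intervals(self):
        s = ibi_summary(_series([1.0] * 10))
        assert (s.mean_ibi, s.median_ibi, s.sd_ibi) == (1.0, 1.0, 0.0)
        assert (s.prop_gt5, s.prop_gt10) == (0.0, 0.0)

    def test_worked_example(self):
        s = ibi_summary(_series([0.8, 1.0, 1.2, 6.0, 12.0]))
        assert s.mean_ibi == pytest.approx(4.2)
        assert s.median_ibi == pytest.approx(1.2)
        assert s.prop_gt5 == pytest.approx(0.4)
        assert s.prop_gt10 == pytest.approx(0.2)
        assert s.sd_ibi == pytest.approx(4.8703, abs=1e-3)  # sample SD (ddof=1)

    def test_strict_inequality_at_boundary(self):
        s = ibi_summary(_series([5.0, 10.0, 5.1, 10.1]))
        assert s.prop_gt5 == pytest.approx(0.75)  # 10.0, 5.1, 10.1 but not 5.0
        assert s.prop_gt10 == pytest.approx(0.25)

    def test_invalid_only_errors(self):
        with pytest.raises(ValueError):
            ibi_summary(_series([1.0, 2.0], valid=[False, False]))

    def test_only_valid_intervals_counted(self):
        s = ibi_summary(_series([1.0, 50.0, 1.0], valid=[True, False, True]))
        assert s.mean_ibi == 1.0 and s.n_ibis == 2


class TestPairedPermutation:
    def test_identical_epochs_give_p_one(self):
        r = paired_permutation_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.t_statistic == 0.0
        assert r.p_uncorrected == 1.0

    def test_exhaustive_one_sided_sixteenth(self):
        """n=4 all-positive differences: only the identity flip reaches t."""
        r = paired_permutation_test(
            [0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0], alternative="greater"
        )
        assert r.exact and r.n_permutations == 16
        assert r.p_uncorrected == 1 / 16

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, size=6)

        def tstat(v):
            v = np.asarray(v)
            return v.mean() / (v.std(ddof=1) / np.sqrt(v.size))

        t_obs = tstat(d)
        count = sum(
            abs(tstat(np.array(signs) * d)) >= abs(t_obs) - 1e-12
            for signs in itertools.product([-1, 1], repeat=6)
        )
        r = paired_permutation_test(np.zeros(6), d)
        assert r.p_uncorrected == pytest.approx(count / 64)

    def test_sign_symmetry_two_sided(self):
        b = np.zeros(10)
        a = np.array([0.5, 1.0, -0.2, 0.8, 1.2, 0.3, -0.1, 0.9, 0.4, 0.7])
        r_pos = paired_permutation_test(b, a, n_perm=2000, seed=9)
        r_neg = paired_permutation_test(b, -a, n_perm=2000, seed=9)
        assert r_neg.t_statistic == pytest.approx(-r_pos.t_statistic)
        assert r_neg.p_uncorrected == r_pos.p_uncorrected

    def test_invariance_to_common_shift_and_order(self):
        rng = np.random.default_rng(5)
        b = rng.normal(size=12)
        a = b + rng.normal(0.4, 1.0, size=12)
        r1 = paired_permutation_test(b, a, n_perm=1000, seed=2)
        r2 = paired_permutation_test(b + 100.0, a + 100.0, n_perm=1000, seed=2)
        assert r1.p_uncorrected == r2.p_uncorrected
        perm = rng.permutation(12)
        r3 = paired_permutation_test(b[perm], a[perm], n_perm=1000, seed=2)
        assert r3.t_statistic == pytest.approx(r1.t_statistic)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        b, a = rng.normal(size=20), rng.normal(size=20)
        r1 = paired_permutation_test(b, a, n_perm=500, seed=4)
        r2 = paired_permutation_test(b, a, n_perm=500, seed=4)
        assert r1.p_uncorrected == r2.p_uncorrected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_permutation_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_permutation_test([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_permutation_test([1, 2], [3, 4], n_perm=10)


class TestHochberg:
    def test_single_p_unchanged(self):
        assert hochberg_correct([0.04])[0] == pytest.approx(0.04)

    def test_worked_step_up(self):
        assert np.allclose(hochberg_correct([0.01, 0.03, 0.04]), [0.03, 0.04, 0.04])

    def test_equal_ps_keep_value(self):
        assert np.allclose(hochberg_correct([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def _brute(self, p):
        """Step-up recursion written independently, largest-first."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")[::-1]  # descending
        adj_sorted = np.empty(m)
        running = np.inf
        for rank, idx in enumerate(order):
            mult = rank + 1  # 1 for the largest p
            running = min(running, mult * p[idx])
            adj_sorted[idx] = min(running, 1.0)
        return adj_sorted

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            m = int(rng.integers(1, 11))
            p = rng.uniform(1e-6, 1.0, size=m)
            ours = hochberg_correct(p)
            assert np.allclose(ours, self._brute(p), atol=1e-12)
            sm = multipletests(p, method="simes-hochberg")[1]
            assert np.allclose(ours, sm, atol=1e-12)

    def test_properties(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1.0, size=8)
        adj = hochberg_correct(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # order-preserving

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hochberg_correct([0.0, 0.5])


class TestCompareSummaries:
    def _summary(self, shift=0.0):
        return IBISummary(
            mean_ibi=1.0 + shift,
            median_ibi=0.9 + shift,
            sd_ibi=0.5 + shift,
            prop_gt5=0.01 + shift / 100,
            prop_gt10=0.002 + shift / 100,
            mean_rr=50.0 - shift,
            n_ibis=300,
        )

    def test_identical_epochs_all_p_one(self):
        before = {f"s{i}": self._summary(0.01 * i) for i in range(6)}
        cmp_ = compare_summaries(before, dict(before), n_perm=500, seed=1)
        for metric in EPOCH_METRICS:
            assert cmp_.results[metric].p_corrected == 1.0

    def test_mismatched_subjects_error(self):
        before = {"a": self._summary(), "b": self._summary()}
        after = {"a": self._summary(), "c": self._summary()}
        with pytest.raises(ValueError):
            compare_summaries(before, after)

    def test_corrected_ge_uncorrected(self):
        rng = np.random.default_rng(2)
        before = {f"s{i}": self._summary(rng.normal(0, 0.05)) for i in range(10)}
        after = {f"s{i}": self._summary(0.2 + rng.normal(0, 0.05)) for i in range(10)}
        cmp_ = compare_summaries(before, after, n_perm=1000, seed=3)
        for metric in EPOCH_METRICS:
            r = cmp_.results[metric]
            assert r.p_corrected >= r.p_uncorrected - 1e-15
        table = cmp_.to_frame()
        assert list(table["metric"]) == list(EPOCH_METRICS)


def test_epoch_summary_runs_pipeline(clean_recording):
    rec, _ = clean_recording
    s = epoch_summary(rec, (0.0, 150.0))
    assert 40.0 <= s.mean_rr <= 50.0
    assert 0.8 <= s.mean_ibi <= 1.8
    assert s.n_ibis > 80
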