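"""Run-length dwell statistics and transition-frequency tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from astigtrack.mobility import JumpSequence
from astigtrack.states import (
    classify,
    dwell_significance,
    find_dwells,
    prob_no_run,
    scan_thresholds,
    transition_stats,
)

DT = 0.0165


def enum_prob_no_run(n, k, p):
    """Exhaustive-enumeration oracle: weight of sequences without a ≥k run."""
    total = 0.0
    for bits in range(2**n):
        run = best = ones = 0
        for i in range(n):
            if (bits >> i) & 1:
                run += 1
                ones += 1
                best = max(best, run)
            else:
                run = 0
        if best < k:
            total += p**ones * (1 - p) ** (n - ones)
    return total


class TestProbNoRun:
    def test_matches_enumeration_small_n(self):
        for n in range(1, 13):
            # precompute max-run per bit pattern once per n
            maxrun = np.empty(2**n, dtype=np.int64)
            ones = np.empty(2**n, dtype=np.int64)
            for bits in range(2**n):
                run = best = o = 0
                for i in range(n):
                    if (bits >> i) & 1:
                        run += 1
                        o += 1
                        best = max(best, run)
                    else:
                        run = 0
                maxrun[bits] = best
                ones[bits] = o
            for p in (0.1, 0.3, 0.5, 0.7, 0.9):
                weights = p**ones * (1 - p) ** (n - ones)
                for k in range(1, n + 1):
                    want = float(weights[maxrun < k].sum())
                    got = prob_no_run(n, k, p)
                    assert abs(got - want) <= 1e-12, (n, k, p)

    def test_k_larger_than_n_is_one(self):
        assert prob_no_run(5, 6, 0.7) == 1.0

    def test_degenerate_probabilities(self):
        assert prob_no_run(10, 3, 0.0) == 1.0
        assert prob_no_run(10, 3, 1.0) == 0.0
        assert prob_no_run(3, 4, 1.0) == 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            prob_no_run(5, 2, 1.5)
        with pytest.raises(ValueError):
            prob_no_run(0, 1, 0.5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(1, 14),
        k=st.integers(1, 14),
        p=st.floats(0.01, 0.99, allow_nan=False),
    )
    def test_probability_bounds_and_enumeration(self, n, k, p):
        val = prob_no_run(n, k, p)
        assert 0.0 <= val <= 1.0
        if n <= 10:
            assert abs(val - enum_prob_no_run(n, min(k, n + 1), p)) <= 1e-10 or k > n


class TestDwellSignificance:
    def test_tiny_cases_by_hand(self):
        # n=1, k=1: only outcome with a run is 'A' itself
        assert dwell_significance(1, 1, 0.3) == pytest.approx(0.3, abs=1e-12)
        # n=2, k=2: only AA of the 4 outcomes
        assert dwell_significance(2, 2, 0.5) == pytest.approx(0.25, abs=1e-12)

    def test_monotone_in_k_p_n(self):
        ks = [2, 4, 8, 16, 32]
        vals = [dwell_significance(200, k, 0.5) for k in ks]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        ps = [0.2, 0.4, 0.6, 0.8]
        vals = [dwell_significance(200, 10, p) for p in ps]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        ns = [50, 100, 200, 400]
        vals = [dwell_significance(n, 10, 0.5) for n in ns]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_monte_carlo_agreement_at_worked_example(self):
        """Fraction of simulated Bernoulli sequences containing a ≥26 run."""
        from scipy.optimize import brentq

        p_star = brentq(lambda p: dwell_significance(221, 26, p) - 5.2e-5, 1e-6, 0.999999)
        rng = np.random.default_rng(7)
        n_sim = 100000
        arr = (rng.random((n_sim, 221)) < p_star).astype(np.int8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, 26, axis=1)
        frac = float((windows.sum(axis=2) == 26).any(axis=1).mean())
        analytic = dwell_significance(221, 26, p_star)
        se = math.sqrt(analytic * (1 - analytic) / n_sim)
        assert abs(frac - analytic) <= 3 * se


class TestClassify:
    def test_all_below_threshold(self):
        seq = classify(JumpSequence(np.full(20, 0.01), DT), 0.5)
        assert seq.p_a == 1.0 and np.all(seq.labels)

    def test_median_threshold_half(self):
        rng = np.random.default_rng(1)
        r2 = rng.exponential(0.05, 100)
        seq = classify(JumpSequence(r2, DT), float(np.median(r2)))
        assert seq.p_a == pytest.approx(0.5, abs=0.01)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.001, 0.5))
    def test_p_a_is_ecdf_at_threshold(self, seed, lim):
        rng = np.random.default_rng(seed)
        r2 = rng.exponential(0.1, 64)
        seq = classify(JumpSequence(r2, DT), lim)
        assert seq.p_a == pytest.approx(np.mean(r2 <= lim))


class TestFindDwells:
    def test_alternating_runs_all_length_one(self):
        labels = np.arange(40) % 2 == 0
        r2 = np.where(labels, 0.01, 1.0)
        seq = classify(JumpSequence(r2, DT), 0.5)
        events = find_dwells(seq)
        assert all(e.length == 1 for e in events)
        assert not any(e.significant() for e in events)

    def test_inserted_immobile_segment_flagged(self):
        rng = np.random.default_rng(0)
        r2 = rng.exponential(4 * 1.0 * DT, 250)
        r2[100:130] = rng.exponential(4 * 0.01 * DT, 30)
        jumps = JumpSequence(r2, DT)
        seq = classify(jumps, float(np.quantile(r2, 0.2)))
        hits = [e for e in find_dwells(seq) if e.state == "A" and e.significant()]
        assert any(e.start >= 95 and e.start + e.length <= 135 for e in hits)

    def test_all_same_state_degenerate(self):
        seq = classify(JumpSequence(np.full(30, 0.01), DT), 0.5)
        events = find_dwells(seq)
        assert len(events) == 1
        assert events[0].length == 30
        assert events[0].p_value == 1.0  # p_A = 1: a full-length run is certain


class TestScanThresholds:
    def test_too_few_jumps_raises(self):
        with pytest.raises(ValueError):
            scan_thresholds(JumpSequence(np.ones(5), DT))

    def test_detects_inserted_dwells(self):
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r2 = rng.exponential(4 * 1.0 * DT, 300)
            r2[100:130] = rng.exponential(4 * 0.02 * DT, 30)
            events = scan_thresholds(JumpSequence(r2, DT))
            detected += any(
                max(e.start, 100) < min(e.start + e.length, 130) and e.length >= 15
                for e in events
            )
        assert detected >= 4

    def test_fixed_threshold_false_positive_rate_near_alpha(self):
        """The exact run test at one threshold is correctly sized (conservative)."""
        alpha = 0.05
        fp = 0
        trials = 200
        for s in range(trials):
            rng = np.random.default_rng(5000 + s)
            r2 = rng.exponential(4 * 1.0 * DT, 250)
            seq = classify(JumpSequence(r2, DT), float(np.median(r2)))
            fp += any(e.state == "A" and e.p_value < alpha for e in find_dwells(seq))
        rate = fp / trials
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / trials)

    def test_events_deduplicated(self):
        rng = np.random.default_rng(3)
        r2 = rng.exponential(4 * 1.0 * DT, 300)
        r2[50:90] = rng.exponential(4 * 0.01 * DT, 40)
        events = scan_thresholds(JumpSequence(r2, DT))
        # overlapping same-state events are merged: no two share an index range
        for a, b in itertools.combinations(events, 2):
            if a.state == b.state:
                assert a.start + a.length <= b.start or b.start + b.length <= a.start


class TestTransitionStats:
    def test_expectation_arithmetic(self):
        r2 = np.concatenate([np.full(50, 0.01), np.full(50, 1.0)])
        rng = np.random.default_rng(0)
        rng.shuffle(r2)
        seq = classify(JumpSequence(r2, DT), 0.5)
        stats = transition_stats(seq)
        assert seq.p_a == 0.5
        assert stats.s_expected == pytest.approx(2 * 0.5 * 0.5 * 100)
        assert stats.sigma == pytest.approx(math.sqrt(0.5 * 0.5 * 100))

    def test_alternating_counts_n_minus_1(self):
        r2 = np.where(np.arange(60) % 2 == 0, 0.01, 1.0)
        seq = classify(JumpSequence(r2, DT), 0.5)
        assert transition_stats(seq).s_observed == 59

    def test_two_sigma_tail_probability(self):
        # a 2-sigma transition deficit corresponds to a one-sided normal tail
        assert float(norm.sf(2.0)) == pytest.approx(0.02275, abs=1e-4)
        r2 = np.concatenate([np.full(30, 0.01), np.full(30, 1.0)])  # one transition
        seq = classify(JumpSequence(r2, DT), 0.5)
        stats = transition_stats(seq)
        assert stats.tail_probability == pytest.approx(float(norm.sf(stats.z_deficit)))
        assert stats.z_deficit > 2.0 and stats.tail_probability < 0.023

    def test_degenerate_flag(self):
        seq = classify(JumpSequence(np.full(20, 0.01), DT), 0.5)
        stats = transition_stats(seq)
        assert stats.degenerate and stats.s_observed == 0

    def test_iid_transition_count_matches_expectation(self):
        """Observed transitions on i.i.d. draws: mean 2*p*q*(n-1) within 3 s.e."""
        p, n, trials = 0.3, 200, 400
        rng = np.random.default_rng(11)
        counts = []
        for _ in range(trials):
            labels = rng.random(n) < p
            counts.append(int(np.count_nonzero(labels[1:] != labels[:-1])))
        mean = np.mean(counts)
        want = 2 * p * (1 - p) * (n - 1)
        se = np.std(counts, ddof=1) / math.sqrt(trials)
        assert abs(mean - want) < 3 * se
        # the conventional form (n instead of n-1) differs by O(1/n)
        assert abs(want - 2 * p * (1 - p) * n) / want < 0.01


class TestNumericalStability:
    def test_recurrence_and_sum_agree_in_overlap(self):
        # both evaluation routes are exact formulas for the same probability;
        # where the alternating sum is numerically safe they must coincide
        from astigtrack.states import _prob_no_run_recurrence

        for n in (20, 50, 100):
            for k in (3, 5, 10):
                for p in (0.2, 0.5, 0.8):
                    a = prob_no_run(n, k, p)
                    b = _prob_no_run_recurrence(n, k, p)
                    assert a == pytest.approx(b, abs=1e-9), (n, k, p)

    def test_large_n_small_k_closed_form(self):
        # k = 1 has the closed form (1-p)^n; the alternating sum has ~n/2
        # cancelling terms here and must be evaluated by the stable route
        for n in (250, 599):
            for p in (0.002, 0.5, 0.97):
                assert prob_no_run(n, 1, p) == pytest.approx((1 - p) ** n, abs=1e-9)

    def test_scan_on_long_brownian_trajectory_is_sane(self):
        # regression: cancellation artefacts once flagged every single jump
        # as an infinitely significant dwell on featureless data
        rng = np.random.default_rng(42)
        r2 = rng.exponential(4 * 1.0 * DT, 599)
        events = scan_thresholds(JumpSequence(r2, DT))
        assert all(e.length >= 5 for e in events)
        assert len(events) < 5
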