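"""Agreement statistics vs an independent brute-force oracle.

The oracle functions below implement the textbook formulas directly
(explicit sums, itertools assignment search) and never call the package
code they check.
"""

import itertools
import math

import numpy as np
import pytest

from depthresp.errors import EvaluationError
from depthresp.estimation import BreathEstimates
from depthresp.evaluation import (
    BreathPairSet,
    agreement_report,
    bland_altman,
    match_breaths,
    mean_absolute_relative_error,
    rr_error_count,
)

# ---------------------------------------------------------------- oracles


def oracle_mare(est, ref):
    return 100.0 * sum(abs(e - r) / r for e, r in zip(est, ref)) / len(est)


def oracle_bland_altman(est, ref, alpha=0.05):
    from scipy.stats import pearsonr, t

    d = [e - r for e, r in zip(est, ref)]
    m = [(e + r) / 2 for e, r in zip(est, ref)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((x - bias) ** 2 for x in d) / (n - 1))
    tcrit = t.ppf(1 - alpha / 2, n - 1)
    ci = (bias - tcrit * sd / math.sqrt(n), bias + tcrit * sd / math.sqrt(n))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    r, p = pearsonr(m, d)
    return bias, ci, loa, float(r), float(p)


def oracle_best_assignment(est_times, ref_times, window):
    """Exhaustive max-cardinality matching within the window."""
    best = 0
    idx_ref = range(len(ref_times))
    for k in range(min(len(est_times), len(ref_times)), 0, -1):
        for est_sub in itertools.combinations(range(len(est_times)), k):
            for ref_sub in itertools.permutations(idx_ref, k):
                if all(abs(est_times[i] - ref_times[j]) <= window
                       for i, j in zip(est_sub, ref_sub)):
                    return k
        if best:
            break
    return best


def _estimates(times, tv=None, rr=None):
    times = np.asarray(times, float)
    tv = np.full(times.size, 0.5) if tv is None else np.asarray(tv, float)
    rr = np.full(times.size, 15.0) if rr is None else np.asarray(rr, float)
    return BreathEstimates(times, tv, rr, tv.copy())


def _pairs(est_tv, ref_tv, est_rr=None, ref_rr=None):
    est_tv = np.asarray(est_tv, float)
    ref_tv = np.asarray(ref_tv, float)
    n = est_tv.size
    est_rr = np.full(n, 15.0) if est_rr is None else np.asarray(est_rr, float)
    ref_rr = np.full(n, 15.0) if ref_rr is None else np.asarray(ref_rr, float)
    return BreathPairSet(est_tv, ref_tv, est_rr, ref_rr, np.zeros(n))


# ----------------------------------------------------------------- tests


class TestMatchBreaths:
    def test_identical_times_all_matched(self):
        t = [2.0, 6.0, 10.0]
        pairs = match_breaths(_estimates(t), _estimates(t))
        assert pairs.n_pairs == 3
        np.testing.assert_allclose(pairs.match_dt_s, 0.0)

    def test_uniform_shift_within_window(self):
        t = np.array([2.0, 6.0, 10.0])
        pairs = match_breaths(_estimates(t + 0.3), _estimates(t))
        np.testing.assert_allclose(pairs.match_dt_s, 0.3)

    def test_missing_breath_matches_optimal_assignment(self):
        ref_t = np.arange(10) * 4.0
        est_t = np.delete(ref_t, 4) + 0.1
        pairs = match_breaths(_estimates(est_t), _estimates(ref_t))
        assert pairs.n_pairs == 9 == oracle_best_assignment(
            list(est_t), list(ref_t), 2.0)
        assert pairs.n_unmatched_ref == 1
        assert pairs.n_unmatched_est == 0

    def test_no_overlap_is_evaluation_error(self):
        with pytest.raises(EvaluationError):
            match_breaths(_estimates([0.0, 1.0]), _estimates([100.0, 104.0]))


class TestMare:
    def test_hand_values(self):
        assert mean_absolute_relative_error(
            _pairs([0.9, 1.1], [1.0, 1.0])) == pytest.approx(10.0)
        assert mean_absolute_relative_error(
            _pairs([1.0], [1.0])) == pytest.approx(0.0)
        assert mean_absolute_relative_error(
            _pairs([1.5], [1.0])) == pytest.approx(50.0)

    def test_scaling_relation(self):
        ref = np.array([0.4, 0.7, 1.2])
        c = 1.17
        assert mean_absolute_relative_error(
            _pairs(c * ref, ref)) == pytest.approx(100 * (c - 1))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(EvaluationError):
            mean_absolute_relative_error(_pairs([1.0], [0.0]))


class TestBlandAltman:
    def test_identity_degenerate(self):
        bias, ci, loa, r, p, degen = bland_altman(_pairs([1, 1.2, 0.8],
                                                         [1, 1.2, 0.8]))
        assert degen
        assert bias == 0 and ci == (0, 0) and loa == (0, 0)

    def test_three_pair_hand_example(self):
        bias, ci, _, _, _, _ = bland_altman(
            _pairs([1.1, 1.2, 1.3], [1.0, 1.0, 1.0]))
        assert bias == pytest.approx(0.2)
        half = 4.302652729911275 * 0.1 / math.sqrt(3)
        assert ci[0] == pytest.approx(0.2 - half, abs=1e-9)
        assert ci[1] == pytest.approx(0.2 + half, abs=1e-9)

    def test_proportional_bias_detected(self, rng):
        n = 100
        ref = rng.uniform(0.3, 1.5, n)
        est = ref + 0.1 * ref + rng.normal(0, 0.01, n)
        pairs = _pairs(est, ref)
        *_, r, p, _ = bland_altman(pairs)
        assert p < 0.05 and r > 0
        # independent check of the correlation test
        from scipy.stats import pearsonr

        r2, p2 = pearsonr((est + ref) / 2, est - ref)
        assert r == pytest.approx(float(r2), abs=1e-12)
        assert p == pytest.approx(float(p2), abs=1e-12)

    def test_antisymmetry_under_swap(self, rng):
        est = rng.uniform(0.3, 1.5, 15)
        ref = est + rng.normal(0, 0.1, 15)
        b1, ci1, loa1, r1, _, _ = bland_altman(_pairs(est, ref))
        b2, ci2, loa2, r2, _, _ = bland_altman(_pairs(ref, est))
        assert b2 == pytest.approx(-b1)
        assert ci2 == pytest.approx((-ci1[1], -ci1[0]))
        assert loa2 == pytest.approx((-loa1[1], -loa1[0]))
        assert r2 == pytest.approx(-r1)

    def test_matches_oracle_on_20_pairs(self, rng):
        est = rng.uniform(0.2, 1.8, 20)
        ref = est + rng.normal(0, 0.15, 20)
        pairs = _pairs(est, ref)
        got = bland_altman(pairs)
        bias, ci, loa, r, p = oracle_bland_altman(list(est), list(ref))
        assert got[0] == pytest.approx(bias, abs=1e-9)
        assert got[1] == pytest.approx(ci, abs=1e-9)
        assert got[2] == pytest.approx(loa, abs=1e-9)
        assert got[3] == pytest.approx(r, abs=1e-9)
        assert got[4] == pytest.approx(p, abs=1e-9)


class TestRRErrorCount:
    def test_difference_above_threshold_counts(self):
        errors, total = rr_error_count(_pairs([1], [1], [15.5], [14.2]))
        assert (errors, total) == (1, 1)

    def test_exactly_one_bpm_is_not_an_error(self):
        errors, _ = rr_error_count(_pairs([1], [1], [15.0], [14.0]))
        assert errors == 0

    def test_identical_rates_clean(self):
        rr = np.full(20, 13.0)
        assert rr_error_count(_pairs(np.ones(20), np.ones(20), rr, rr)) == (0, 20)


class TestAgreementReport:
    def test_full_report_consistency(self, rng):
        est = rng.uniform(0.3, 1.4, 20)
        ref = est + rng.normal(0, 0.1, 20)
        pairs = _pairs(est, ref, np.full(20, 12.0), np.full(20, 12.5))
        rep = agreement_report(pairs)
        assert rep.mare_pct == pytest.approx(oracle_mare(est, ref), abs=1e-9)
        assert rep.rr_errors == 0 and rep.rr_total == 20
        assert rep.loa_L[0] <= rep.bias_L <= rep.loa_L[1]
        assert rep.n_pairs == 20
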