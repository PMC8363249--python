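"""Beat matching, detection statistics, Bland-Altman, fHR traces."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fecgkit import (
    AnnotationSet,
    MatchCounts,
    bland_altman,
    clopper_pearson,
    compute_metrics,
    fhr_trace,
    match_peaks,
)
from fecgkit.errors import ParameterError


def _ann(indices, fs=1000.0):
    return AnnotationSet(np.asarray(indices), fs)


def _optimal_tp(ref, det, tol_samples):
    """Brute-force maximum one-to-one matching (oracle for small instances)."""

    def go(i, used):
        if i == len(ref):
            return 0
        best = go(i + 1, used)
        for j, d in enumerate(det):
            if j not in used and abs(d - ref[i]) <= tol_samples:
                best = max(best, 1 + go(i + 1, used | {j}))
        return best

    return go(0, frozenset())


class TestMatchPeaks:
    def test_hand_worked_example(self):
        c = match_peaks(_ann([100, 200, 300]), _ann([101, 205, 400]))
        assert (c.TP, c.FP, c.FN) == (2, 1, 1)

    def test_perfect_detection(self):
        c = match_peaks(_ann([10, 50, 90]), _ann([10, 50, 90]))
        assert (c.TP, c.FP, c.FN) == (3, 0, 0)

    def test_one_to_one_constraint(self):
        c = match_peaks(_ann([100]), _ann([90, 110]))
        assert (c.TP, c.FP, c.FN) == (1, 1, 0)

    def test_mismatched_rates_rejected(self):
        with pytest.raises(ParameterError):
            match_peaks(_ann([1], 500.0), _ann([1], 1000.0))

    def test_greedy_equals_optimal_on_beat_like_instances(self):
        """1000 seeded trials of realistic beat trains (RR >= 0.25 s, 50 ms
        detection jitter, drops and extras) where greedy nearest-first
        matching is provably optimal."""
        rng = np.random.default_rng(99)
        tol = 0.05
        for _ in range(1000):
            n_ref = rng.integers(1, 9)
            rr = rng.uniform(0.25, 1.0, n_ref)
            ref = np.cumsum(rr) * 1000
            keep = rng.random(n_ref) > 0.2
            det = ref[keep] + rng.uniform(-60, 60, keep.sum())
            extra = rng.uniform(0, ref[-1], rng.integers(0, 3))
            det = np.unique(np.round(np.concatenate([det, extra]))).astype(int)
            ref = np.round(ref).astype(int)
            c = match_peaks(_ann(ref), _ann(det))
            assert c.TP == _optimal_tp(list(ref), list(det), tol * 1000)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (679, 1, 5, (99.12, 99.27, 99.85, 99.56)),
            (40, 50, 90, (22.22, 30.77, 44.44, 36.36)),
        ],
    )
    def test_benchmark_rows(self, tp, fp, fn, expected):
        m = compute_metrics(MatchCounts.from_counts(tp, fp, fn))
        got = (m.acc, m.se, m.ppv, m.f1)
        assert np.allclose(np.round(got, 2), expected)

    def test_degenerate_counts_flag_undefined(self):
        m = compute_metrics(MatchCounts.from_counts(0, 0, 5))
        assert m.acc == 0.0 and m.se == 0.0
        assert math.isnan(m.ppv) and "PPV" in m.undefined

    def test_all_zero_flags_everything(self):
        m = compute_metrics(MatchCounts.from_counts(0, 0, 0))
        assert m.undefined == {"ACC", "SE", "PPV", "F1"}

    @given(st.integers(1, 2000), st.integers(0, 300), st.integers(0, 300))
    def test_f1_is_harmonic_mean_of_se_and_ppv(self, tp, fp, fn):
        m = compute_metrics(MatchCounts.from_counts(tp, fp, fn))
        harmonic = 2 * m.se * m.ppv / (m.se + m.ppv)
        assert abs(m.f1 - harmonic) <= 1e-9


class TestClopperPearson:
    def test_boundary_interval_all_successes(self):
        lo, hi = clopper_pearson(644, 644)
        assert round(lo, 2) == 99.43 and hi == 100.0

    def test_boundary_interval_doubled_denominator(self):
        lo, _ = clopper_pearson(1288, 1288)
        assert round(lo, 2) == 99.71

    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert abs(hi - 100 * (1 - 0.025 ** (1 / 10))) <= 1e-9

    def test_zero_trials_rejected(self):
        with pytest.raises(ParameterError):
            clopper_pearson(0, 0)


class TestBlandAltman:
    def test_hand_computed_limits(self):
        ref = np.zeros(5)
        est = np.array([1.0, -1.0, 0.0, 2.0, -2.0])
        ba = bland_altman(ref, est)
        assert abs(ba.mu) <= 1e-12
        assert abs(ba.loa_upper - 3.099) <= 0.005
        assert abs(ba.loa_lower + 3.099) <= 0.005

    def test_identical_series(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mu == 0.0 and ba.loa_upper == 0.0 and ba.loa_lower == 0.0

    def test_constant_offset(self):
        ba = bland_altman([1.0, 2.0, 3.0], [6.0, 7.0, 8.0])
        assert ba.mu == 5.0 and ba.sigma == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_ordering_invariant(self, rng):
        d = rng.standard_normal(40)
        ba = bland_altman(np.zeros(40), d)
        assert ba.loa_lower <= ba.mu <= ba.loa_upper


class TestFhrTrace:
    def _uniform_ann(self, rr_s, n=40, fs=1000.0):
        return AnnotationSet(np.arange(1, n + 1) * int(rr_s * fs), fs)

    def test_constant_rr_gives_constant_rate(self):
        trace = fhr_trace(self._uniform_ann(0.4))
        assert np.allclose(trace.rate, 150.0)
        assert set(trace.zones) == {"physiological"}

    def test_120_bpm_is_physiological(self):
        trace = fhr_trace(self._uniform_ann(0.5))
        assert np.allclose(trace.rate, 120.0)
        assert set(trace.zones) == {"physiological"}

    def test_zone_bands(self):
        from fecgkit.metrics import _zone

        assert _zone(70.0) == "high-risk" and _zone(190.0) == "high-risk"
        assert _zone(85.0) == "increased-risk" and _zone(100.0) == "increased-risk"
        assert _zone(160.0) == "increased-risk"
        assert _zone(110.0) == "physiological" and _zone(150.0) == "physiological"

    def test_moving_average_suppresses_alternans(self):
        rr = np.tile([0.4, 0.5], 40)
        ann = AnnotationSet(np.round(np.cumsum(rr) * 1000).astype(int), 1000.0)
        trace = fhr_trace(ann)
        raw_amp = np.ptp(trace.raw_rate[15:-15])
        smooth_amp = np.ptp(trace.rate[15:-15])
        assert np.all((trace.rate >= 120.0 - 1e-9) & (trace.rate <= 150.0 + 1e-9))
        assert smooth_amp <= raw_amp / 10

    def test_too_few_beats_rejected(self):
        with pytest.raises(ParameterError):
            fhr_trace(self._uniform_ann(0.4, n=20))
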