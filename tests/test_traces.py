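"""ΔF/F computation, Gaussian FWHM fitting, ECDFs and response averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from astrocal.io import MovieStack
from astrocal.traces import (EcdfSummary, Trace, average_response, build_ecdfs,
                             compute_trace, fit_events, ks_distance,
                             lower_quartile_baseline)

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _movie_from_trace(values):
    """Single-pixel-ROI movie whose ROI trace equals ``values``."""
    data = np.asarray(values, dtype=float)[:, None, None] * np.ones((1, 3, 3))
    return MovieStack(data, 1.0, 0.5)


def _trace(dfof, dt=0.5, F0=1.0):
    dfof = np.asarray(dfof, dtype=float)
    return Trace(0, F0 * (1 + dfof), F0, dfof, dt)


class TestComputeTrace:
    def test_constant_trace_gives_zero_dfof(self):
        tr = compute_trace(_movie_from_trace([5.0] * 8), {(1, 1)})
        assert tr.F0 == 5.0
        assert np.all(tr.dFoF == 0.0)

    def test_lower_quartile_worked_example(self):
        """F = [1,1,1,3]: the lower-quartile set is the three 1s, so F0 = 1
        and ΔF/F = [0,0,0,2]."""
        tr = compute_trace(_movie_from_trace([1.0, 1.0, 1.0, 3.0]), {(1, 1)})
        assert tr.F0 == 1.0
        np.testing.assert_array_equal(tr.dFoF, [0.0, 0.0, 0.0, 2.0])

    def test_single_transient_max_dfof(self):
        F = [100.0] * 19 + [150.0]
        tr = compute_trace(_movie_from_trace(F), {(1, 1)})
        assert tr.dFoF.max() == pytest.approx(0.5)

    def test_background_subtraction_disjointness(self):
        movie = _movie_from_trace([10.0] * 8)
        with pytest.raises(ValueError, match="disjoint"):
            compute_trace(movie, {(1, 1)}, {(1, 1)})

    def test_nonpositive_f0_rejected(self):
        data = np.ones((8, 3, 3))
        data[:, 2, 2] = 5.0  # background brighter than ROI
        movie = MovieStack(data, 1.0, 0.5)
        with pytest.raises(ValueError, match="background exceeds"):
            compute_trace(movie, {(0, 0)}, {(2, 2)})

    @given(gain=st.floats(0.1, 100.0))
    def test_dfof_invariant_to_multiplicative_gain(self, gain):
        rng = np.random.default_rng(5)
        F = 100.0 + rng.normal(0, 5, size=32)
        tr1 = compute_trace(_movie_from_trace(F), {(1, 1)})
        tr2 = compute_trace(_movie_from_trace(gain * F), {(1, 1)})
        np.testing.assert_allclose(tr1.dFoF, tr2.dFoF, rtol=1e-9, atol=1e-12)


class TestFitEvents:
    def test_noiseless_gaussian_fwhm_closed_form(self):
        """σ = 2.0 s ⇒ FWHM = 2·sqrt(2 ln 2)·2 = 4.7096 s (4 s.f.)."""
        t = np.arange(80) * 0.5
        dfof = 1.5 * np.exp(-((t - 20.0) ** 2) / (2 * 2.0**2))
        events = fit_events(_trace(dfof), [(0, 79)])
        assert len(events) == 1
        assert events[0].fwhm == pytest.approx(4.70964, rel=5e-5)
        assert events[0].fwhm == pytest.approx(GAUSS_FWHM * events[0].sigma)

    def test_noisy_fwhm_recovery(self):
        """Noise at amplitude/5 on a densely sampled transient (0.1 s):
        median FWHM error below 5% over 50 fits."""
        t = np.arange(400) * 0.1
        true = GAUSS_FWHM * 2.0
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(50):
            dfof = (1.0 * np.exp(-((t - 20.0) ** 2) / (2 * 2.0**2))
                    + rng.normal(0, 0.2, size=t.size))
            events = fit_events(_trace(dfof, dt=0.1), [(0, 399)])
            if events:
                errs.append(abs(events[0].fwhm - true) / true)
        assert len(errs) >= 45
        assert np.median(errs) < 0.05

    def test_flat_window_returns_no_event(self):
        events = fit_events(_trace(np.zeros(20)), [(0, 19)])
        assert events == []

    def test_short_window_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than 5"):
            events = fit_events(_trace(np.ones(20)), [(0, 3)])
        assert events == []


class TestEcdfs:
    def test_ecdf_evaluation(self):
        e = EcdfSummary("v", "c", [1.0, 2.0, 3.0])
        assert e(2.0) == pytest.approx(2 / 3)
        assert e(3.0) == 1.0
        assert e(0.5) == 0.0
        grid = np.linspace(0, 4, 50)
        vals = e(grid)
        assert np.all(np.diff(vals) >= 0)

    def test_identical_samples_zero_ks(self):
        a = EcdfSummary("v", "a", [1.0, 5.0, 2.0])
        b = EcdfSummary("v", "b", [1.0, 5.0, 2.0])
        assert ks_distance(a, b) == 0.0

    def test_ks_matches_scipy(self, rng):
        """Cross-check our sup-difference against scipy.stats.ks_2samp."""
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.7, 1.3, 60)
        ours = ks_distance(EcdfSummary("v", "x", x), EcdfSummary("v", "y", y))
        assert ours == pytest.approx(stats.ks_2samp(x, y).statistic, abs=1e-12)

    def test_build_ecdfs_rejects_empty_condition(self):
        good = pd.DataFrame({"roi_size_um2": [1.0], "max_dfof": [1.0],
                             "fwhm_s": [1.0]})
        empty = good.iloc[:0]
        with pytest.raises(ValueError, match="no events"):
            build_ecdfs({"a": good, "b": empty})

    def test_build_ecdfs_pairwise_table(self):
        t1 = pd.DataFrame({"roi_size_um2": [1.0, 2.0], "max_dfof": [0.5, 0.6],
                           "fwhm_s": [1.0, 2.0]})
        t2 = pd.DataFrame({"roi_size_um2": [10.0, 20.0], "max_dfof": [0.5, 0.6],
                           "fwhm_s": [1.0, 2.0]})
        ecdfs, ks = build_ecdfs({"a": t1, "b": t2})
        assert set(ecdfs) == {(c, v) for c in "ab"
                              for v in ("roi_size_um2", "max_dfof", "fwhm_s")}
        row = ks[(ks.variable == "roi_size_um2")].iloc[0]
        assert row.ks_distance == 1.0


class TestAverageResponse:
    def test_identical_traces(self):
        tr = _trace([0.0, 1.0, 0.5])
        out = average_response([tr, tr])
        np.testing.assert_array_equal(out.mean_dfof, tr.dFoF)
        np.testing.assert_array_equal(out.sem_dfof, 0.0)

    def test_sem_arithmetic(self):
        """Traces [0,2] and [2,0]: mean [1,1]; sample sd √2 so sem = 1."""
        out = average_response([_trace([0.0, 2.0]), _trace([2.0, 0.0])])
        np.testing.assert_allclose(out.mean_dfof, [1.0, 1.0])
        np.testing.assert_allclose(out.sem_dfof, [1.0, 1.0])

    def test_single_trace_sem_missing(self):
        out = average_response([_trace([0.0, 1.0])])
        assert out.sem_dfof.isna().all()

    def test_stimulus_time_rezeroes_axis(self):
        out = average_response([_trace([0.0] * 4), _trace([0.0] * 4)],
                               stimulus_time=1.0)
        np.testing.assert_allclose(out.time_s, [-1.0, -0.5, 0.0, 0.5])

    def test_mismatched_traces_rejected(self):
        with pytest.raises(ValueError, match="share"):
            average_response([_trace([0.0, 1.0]), _trace([0.0, 1.0, 2.0])])
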