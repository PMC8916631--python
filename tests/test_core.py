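"""PTDA pipeline: outlier screening, aggregation, significance, full runs."""

import numpy as np
import pytest

from ptda import PtdaConfig
from ptda.core import (ChangePoint, collect_cps, derive_tp, edge_filter,
                       matrix_change_point, probability_band, remove_outliers,
                       run_ptda, significance_test)


def _cps(positions, method="raw_mean"):
    return [ChangePoint(int(p), method) for p in positions]


class TestRemoveOutliers:
    def test_clean_gaussian_rarely_flagged(self):
        """GESD keeps its nominal size: >= 95% of clean series untouched."""
        rng = np.random.default_rng(5)
        untouched = sum(
            remove_outliers(rng.standard_normal(100))[0].size == 100
            for _ in range(200))
        assert untouched >= 190

    def test_single_big_spike_removed_exactly(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        x[40] += 10.0
        clean, index_map = remove_outliers(x)
        assert clean.size == 99
        assert 41 not in index_map
        assert np.array_equal(clean, np.delete(x, 40))

    def test_index_map_points_to_original_axis(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(50)
        x[10] -= 12.0
        clean, index_map = remove_outliers(x)
        assert all(x[i - 1] == c for c, i in zip(clean, index_map))

    def test_constant_series_untouched(self):
        clean, idx = remove_outliers(np.full(30, 2.0))
        assert clean.size == 30

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.zeros(10))


class TestMatrixChangePoint:
    def test_uniform_step_rows_vote_their_position(self, rng):
        rows = np.tile(np.where(np.arange(100) < 49, 0.0, 1.0), (40, 1))
        rows += 0.01 * rng.standard_normal(rows.shape)
        pos = matrix_change_point(rows)
        assert abs(pos - 50) <= 10            # within half a bin of the step

    def test_constant_rows_give_nothing(self):
        assert matrix_change_point(np.ones((10, 50))) is None

    def test_votes_match_handbuilt_histogram(self, rng):
        """Rows stepping at 50 +/- 2: result sits in the modal bin around 50."""
        steps = rng.integers(48, 53, size=98)
        rows = np.vstack([np.where(np.arange(100) < s - 1, 0.0, 1.0)
                          + 0.01 * rng.standard_normal(100) for s in steps])
        pos = matrix_change_point(rows)
        assert 41 <= pos <= 60

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            matrix_change_point(np.empty((0, 0)))


class TestEdgeFilter:
    @pytest.mark.parametrize("p, kept", [(5, False), (10, False), (11, True),
                                         (50, True), (90, True), (91, False),
                                         (95, False)])
    def test_ten_percent_rule(self, p, kept):
        out = edge_filter(_cps([p]), L=100)
        assert (len(out) == 1) == kept


class TestSignificance:
    def test_perfectly_clustered_cps_are_significant(self):
        sig, real_iqr, _, lower = significance_test(_cps([50] * 6), 100, seed=0)
        assert sig and real_iqr == 0.0 and lower > 0.0

    def test_below_minimum_count_is_negative(self):
        sig, real_iqr, *_ = significance_test(_cps([50, 51]), 100, seed=0)
        assert not sig and real_iqr is None

    def test_size_under_its_own_uniform_null(self):
        """Uniformly scattered CPs pass in only a few percent of trials."""
        rng = np.random.default_rng(11)
        hits = sum(
            significance_test(_cps(rng.integers(1, 101, 6)), 100,
                              seed=int(rng.integers(2 ** 31)))[0]
            for _ in range(2000))
        assert 0.005 <= hits / 2000 <= 0.045

    def test_normal_approximation_bound_available(self):
        sig, _, mean, lower = significance_test(_cps([50] * 5), 100, seed=1,
                                                ci_method="normal")
        assert sig and lower < mean


class TestDeriveTpAndBand:
    def test_median_of_identical_positions(self):
        assert derive_tp(_cps([50, 50, 50])) == 50

    def test_round_half_up_median(self):
        assert derive_tp(_cps([48, 50, 53, 55])) == 52

    def test_band_peak_height_one_per_cp(self):
        band = probability_band(_cps([50]), 100)
        assert band[49] == pytest.approx(1.0)
        assert np.argmax(band) == 49

    def test_coincident_cps_add(self):
        band = probability_band(_cps([50, 50, 50]), 100)
        assert band[49] == pytest.approx(3.0)

    def test_two_distant_cps_make_two_unit_peaks(self):
        band = probability_band(_cps([30, 50]), 100)
        assert band[29] == pytest.approx(1.0, abs=1e-6)
        assert band[49] == pytest.approx(1.0, abs=1e-6)
        assert band[39] < 0.01

    def test_empty_cps_give_zero_band(self):
        assert np.all(probability_band([], 50) == 0.0)


class TestRunPtda:
    def test_constant_recording_reports_no_transition(self, cfg):
        res = run_ptda([np.full(100, 0.3)] * 5, cfg)
        assert res.tp is None and not res.significant and res.cps == []

    def test_five_step_series_recover_the_step(self, cfg, rng):
        series = [np.where(np.arange(100) < 49, 0.0, 1.0)
                  + 0.03 * rng.standard_normal(100) for _ in range(5)]
        res = run_ptda(series, cfg)
        assert res.significant
        assert abs(res.tp - 50) <= 2

    @pytest.mark.parametrize("t", list(range(20, 81, 10)))
    def test_noiseless_step_recovery_across_positions(self, cfg, t):
        x = np.zeros(100)
        x[t:] = 1.0
        res = run_ptda([x], cfg)
        assert res.tp is not None and abs(res.tp - (t + 1)) <= 2

    def test_reported_tp_obeys_edge_rule(self, cfg, small_transition_windows):
        for w in small_transition_windows:
            res = run_ptda([w.data[:, j] for j in range(5)], cfg)
            if res.tp is not None:
                assert 10 < res.tp <= 90
            for cp in res.surviving:
                assert 10 < cp.position <= 90

    def test_pipeline_deterministic_given_seed(self, small_transition_windows):
        w = small_transition_windows[0]
        cols = [w.data[:, j] for j in range(5)]
        a = run_ptda(cols, PtdaConfig(seed=33))
        b = run_ptda(cols, PtdaConfig(seed=33))
        assert a.tp == b.tp and a.real_iqr == b.real_iqr
        assert np.array_equal(a.band, b.band)
        assert [c.position for c in a.cps] == [c.position for c in b.cps]

    def test_length_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError):
            run_ptda([np.zeros(50), np.zeros(60)], cfg)

    def test_outlier_position_never_becomes_the_transition(self, cfg, rng):
        x = 0.2 * rng.standard_normal(100)
        x[70] += 8.0
        res = run_ptda([x], cfg)
        # the spike is deleted before any method runs, so no method may
        # anchor a change point on it
        assert all(abs(cp.position - 71) > 1 for cp in res.cps)
        if res.tp is not None:
            assert abs(res.tp - 71) > 1


class TestCollectCps:
    def test_constant_series_yields_nothing(self, cfg):
        assert collect_cps(np.full(100, 1.0), cfg) == []

    def test_step_series_produces_convergent_methods(self, cfg):
        x = np.where(np.arange(100) < 49, 0.0, 1.0)
        cps = collect_cps(x, cfg)
        methods = {c.method for c in cps}
        assert "raw_mean" in methods
        near = [c for c in cps if abs(c.position - 50) <= 3]
        assert len(near) >= 3
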