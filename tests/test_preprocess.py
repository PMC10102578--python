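import numpy as np
import pandas as pd
import pytest

from breathsig import preprocess as pp
from breathsig import synthdata as sd
from breathsig.io import ScanSeries
from breathsig.preprocess import (
    MZ_GRID_STEP,
    PeakTable,
    align_features,
    detect_exhalations,
    mz_grid,
    normalize_and_log,
    pick_peaks,
    recalibrate_mz,
    resample_spectrum,
)


class TestResample:
    def test_identity_on_grid(self):
        grid = mz_grid()
        lo, hi = 1000, 1040
        mz = grid[lo:hi]
        vals = np.arange(float(hi - lo))
        out = resample_spectrum(mz, vals)
        np.testing.assert_allclose(out[lo:hi], vals, atol=1e-9)
        assert out[: lo - 1].sum() == 0 and out[hi + 1 :].sum() == 0

    def test_triangle_apex_within_one_step(self):
        apex = 123.45678
        mz = np.array([apex - 0.01, apex, apex + 0.01])
        out = resample_spectrum(mz, np.array([0.0, 100.0, 0.0]))
        got = mz_grid()[np.argmax(out)]
        assert abs(got - apex) <= MZ_GRID_STEP

    def test_empty_scan_all_zero(self):
        out = resample_spectrum(np.array([]), np.array([]))
        assert out.shape == (900001,)
        assert out.sum() == 0.0

    def test_non_ascending_rejected(self):
        with pytest.raises(ValueError):
            resample_spectrum(np.array([100.0, 99.0]), np.array([1.0, 2.0]))


class TestDetectExhalations:
    def test_square_wave_three_plateaus(self):
        tic = np.zeros(120)
        truth = [(20, 36), (55, 71), (90, 106)]
        for a, b in truth:
            tic[a:b] = 100.0
        seg = detect_exhalations(tic, scan_period=0.5, min_duration_s=3.0)
        assert len(seg) == 3
        assert not seg.warning
        for (ga, gb), (ta, tb) in zip(seg.segments, truth):
            assert abs(ga - ta) <= 1 and abs(gb - tb) <= 1

    def test_constant_tic_no_segments(self):
        seg = detect_exhalations(np.full(50, 42.0), scan_period=0.5)
        assert len(seg) == 0
        assert seg.warning

    def test_single_dominant_plateau(self):
        tic = np.zeros(100)
        tic[30:70] = 50.0
        seg = detect_exhalations(tic, scan_period=0.5)
        assert len(seg) == 1
        assert seg.segments[0] == (30, 70)
        assert seg.warning  # fewer than three exhalations

    def test_short_blips_dropped(self):
        tic = np.zeros(100)
        tic[10:12] = 100.0  # 1 s at 0.5 s/scan: below min duration
        seg = detect_exhalations(tic, scan_period=0.5, min_duration_s=3.0)
        assert len(seg) == 0

    def test_gap_merging(self):
        tic = np.zeros(100)
        tic[20:30] = 100.0
        tic[32:42] = 100.0  # 2-scan hole gets merged
        seg = detect_exhalations(tic, scan_period=0.5)
        assert seg.segments == [(20, 42)]

    def test_too_few_scans(self):
        with pytest.raises(ValueError):
            detect_exhalations(np.zeros(10), scan_period=0.5)


class TestAverageSpectrum:
    def _series(self, intensities_per_scan):
        grid = mz_grid()
        mz = grid[2000:2005]
        return ScanSeries(
            times=np.arange(len(intensities_per_scan)) * 0.5,
            mz_arrays=[mz] * len(intensities_per_scan),
            intensity_arrays=[np.full(5, v) for v in intensities_per_scan],
        )

    def test_identical_scans(self):
        series = self._series([7.0] * 30)
        seg = pp.ExhalationSegments(segments=[(5, 15)], tic_trace=series.tic())
        avg = pp.average_exhalation_spectrum(series, seg)
        assert avg[2000:2005] == pytest.approx([7.0] * 5)

    def test_two_scan_mean(self):
        series = self._series([2.0, 4.0] + [0.0] * 28)
        seg = pp.ExhalationSegments(segments=[(0, 2)], tic_trace=series.tic())
        avg = pp.average_exhalation_spectrum(series, seg)
        assert avg[2002] == pytest.approx(3.0)

    def test_segment_split_invariance(self):
        series = self._series([5.0] * 30)
        one = pp.ExhalationSegments(segments=[(0, 20)], tic_trace=series.tic())
        two = pp.ExhalationSegments(segments=[(0, 10), (10, 20)], tic_trace=series.tic())
        np.testing.assert_allclose(
            pp.average_exhalation_spectrum(series, one),
            pp.average_exhalation_spectrum(series, two),
        )

    def test_empty_segments_rejected(self):
        series = self._series([1.0] * 25)
        seg = pp.ExhalationSegments(segments=[], tic_trace=series.tic())
        with pytest.raises(ValueError):
            pp.average_exhalation_spectrum(series, seg)


def _gaussian_on_grid(center, sigma, area):
    grid = mz_grid()
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


class TestPickPeaks:
    def test_noiseless_gaussian_area_within_1pct(self):
        spec = _gaussian_on_grid(150.0, 0.003, area=500.0)
        peaks = pick_peaks(spec)
        assert len(peaks) == 1
        row = peaks.table.iloc[0]
        assert row["apex_mz"] == pytest.approx(150.0, abs=MZ_GRID_STEP)
        assert row["area"] == pytest.approx(500.0, rel=0.01)

    def test_flat_baseline_no_peaks(self):
        assert len(pick_peaks(np.zeros(len(mz_grid())))) == 0

    def test_two_resolved_gaussians(self):
        sigma = 0.003
        spec = _gaussian_on_grid(150.0, sigma, 300.0) + _gaussian_on_grid(
            150.0 + 6 * sigma, sigma, 300.0
        )
        peaks = pick_peaks(spec)
        assert len(peaks) == 2
        apexes = sorted(peaks.table["apex_mz"])
        assert apexes[0] == pytest.approx(150.0, abs=2 * MZ_GRID_STEP)
        assert apexes[1] == pytest.approx(150.0 + 6 * sigma, abs=2 * MZ_GRID_STEP)

    def test_wrong_grid_rejected(self):
        with pytest.raises(ValueError):
            pick_peaks(np.zeros(100))

    def test_trapezoid_triangle_exact(self):
        # oracle equivalence: trapezoid rule is exact for piecewise-linear
        # input when the vertices lie on grid points
        grid = mz_grid()
        spec = np.zeros(len(grid))
        apex_idx = 10000
        half = 20
        spec[apex_idx - half : apex_idx + half + 1] = np.concatenate(
            [np.linspace(0, 50, half + 1), np.linspace(50, 0, half + 1)[1:]]
        )
        analytic = 0.5 * (2 * half * MZ_GRID_STEP) * 50.0
        peaks = pick_peaks(spec)
        assert len(peaks) == 1
        assert peaks.table.iloc[0]["area"] == pytest.approx(analytic, rel=1e-12)


def _table(rows):
    return PeakTable(pd.DataFrame(rows, columns=["apex_mz", "left_mz", "right_mz", "area", "apex_intensity"]))


def _simple_table(apexes, areas):
    return _table(
        [
            {"apex_mz": m, "left_mz": m - 0.01, "right_mz": m + 0.01, "area": a, "apex_intensity": a}
            for m, a in zip(apexes, areas)
        ]
    )


class TestAlignFeatures:
    def test_identical_tables(self):
        tables = [_simple_table([100.0, 200.0, 300.0], [1.0, 2.0, 3.0])] * 4
        areas, mzs = align_features(tables, tol_ppm=10)
        assert areas.shape == (4, 3)
        assert not np.any(areas == 0)
        np.testing.assert_allclose(mzs, [100.0, 200.0, 300.0])

    def test_one_ppm_apart_merged(self):
        t1 = _simple_table([200.0], [1.0])
        t2 = _simple_table([200.0 * (1 + 1e-6)], [1.0])
        areas, mzs = align_features([t1, t2], tol_ppm=10)
        assert areas.shape == (2, 1)

    def test_distant_apexes_not_merged(self):
        t1 = _simple_table([200.0], [1.0])
        t2 = _simple_table([200.0 * (1 + 50e-6)], [1.0])
        areas, mzs = align_features([t1, t2], tol_ppm=10, presence_fraction=0.0)
        assert areas.shape == (2, 2)

    def test_rare_feature_dropped(self):
        tables = [_simple_table([100.0], [1.0]) for _ in range(9)]
        tables.append(_simple_table([100.0, 300.0], [1.0, 5.0]))
        areas, mzs = align_features(tables, tol_ppm=10, presence_fraction=0.7)
        assert list(mzs) == [100.0]

    def test_consensus_is_weighted_mean(self):
        t1 = _simple_table([200.0], [3.0])
        t2 = _simple_table([200.0002], [1.0])
        _, mzs = align_features([t1, t2], tol_ppm=10)
        assert mzs[0] == pytest.approx((200.0 * 3 + 200.0002) / 4)

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            align_features([_simple_table([100.0], [1.0])] * 2, tol_ppm=0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            align_features([_simple_table([100.0], [1.0])])


class TestNormalizeAndLog:
    def test_fractions(self):
        bpm = normalize_and_log(np.array([[2.0, 3.0, 5.0]] * 2), [100.0, 200.0, 300.0], ["a", "b"])
        np.testing.assert_allclose(2.0 ** bpm.values[0], [0.2, 0.3, 0.5])

    def test_row_sum_one_before_log(self):
        A = np.abs(np.random.default_rng(0).normal(5, 1, size=(3, 6)))
        bpm = normalize_and_log(A, np.sort(np.random.default_rng(1).uniform(60, 400, 6)), list("abc"))
        np.testing.assert_allclose((2.0 ** bpm.values).sum(axis=1), 1.0)

    def test_scale_invariance_exact(self):
        A = np.array([[1.0, 4.0, 5.0], [2.0, 2.0, 6.0]])
        mz = [100.0, 150.0, 200.0]
        b1 = normalize_and_log(A, mz, ["a", "b"])
        b2 = normalize_and_log(A * 37.5, mz, ["a", "b"])
        np.testing.assert_array_equal(b1.values, b2.values)

    def test_identical_samples_identical_rows(self):
        A = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        bpm = normalize_and_log(A, [100.0, 150.0, 200.0], ["a", "b"])
        np.testing.assert_array_equal(bpm.values[0], bpm.values[1])

    def test_zero_imputed_at_half_minimum(self):
        A = np.array([[0.0, 1.0, 3.0], [1.0, 1.0, 2.0]])
        bpm = normalize_and_log(A, [100.0, 150.0, 200.0], ["a", "b"])
        norm0 = 2.0 ** bpm.values[0]
        assert norm0[0] == pytest.approx(0.25 / 2)  # half of smallest positive (1/4)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_log(np.array([[-1.0, 2.0]]), [100.0, 200.0], ["a"])


class TestRecalibrate:
    def test_two_point_linear(self):
        obs = np.array([100.001, 200.002])
        out = recalibrate_mz(obs, (100.001, 100.0), (200.002, 200.0))
        np.testing.assert_allclose(out, [100.0, 200.0], atol=1e-9)

    def test_identity_when_points_match(self):
        mz = np.array([120.0, 180.0])
        np.testing.assert_allclose(recalibrate_mz(mz, (100.0, 100.0), (200.0, 200.0)), mz)

    def test_degenerate_points(self):
        with pytest.raises(ValueError):
            recalibrate_mz(np.array([100.0]), (150.0, 150.0), (150.0, 151.0))


@pytest.fixture(scope="module")
def pipeline_result():
    cfg = sd.SimConfig(
        n_case=3, n_control=3, n_features=25, n_differential=5,
        noise_sd_log2=0.0, scan_noise_sd=0.0, satellite_fraction=0.0,
        recording_duration=60.0, rng_seed=21,
    )
    cohort, truth = sd.simulate_cohort(cfg)
    recordings = []
    for i, sid in enumerate(cohort.samples["sample_id"]):
        recordings.append(
            sd.simulate_recording(
                2.0 ** cohort.log2_abundance[i], truth.feature_mz, cfg,
                rng=1000 + i, sample_id=sid, baseline_level=0.05,
            )
        )
    bpm, qcs = pp.build_matrix(recordings)
    return cfg, cohort, truth, bpm, qcs


class TestEndToEnd:
    def test_feature_mz_recovered_within_5ppm(self, pipeline_result):
        _, _, truth, bpm, _ = pipeline_result
        planted = np.sort(truth.feature_mz)
        matched = 0
        for mz in planted:
            err = np.min(np.abs(bpm.feature_mz - mz)) / mz * 1e6
            matched += err <= 5.0
        assert matched / len(planted) >= 0.99

    def test_qc_reports_three_exhalations(self, pipeline_result):
        *_, qcs = pipeline_result
        assert all(q.n_exhalations == 3 for q in qcs)
        assert all(not q.warning for q in qcs)

    def test_log2_areas_monotone_in_abundance(self, pipeline_result):
        from scipy.stats import spearmanr

        _, cohort, truth, bpm, _ = pipeline_result
        planted = np.asarray(truth.feature_mz)
        # map each recovered feature to the nearest planted one
        for row in range(len(bpm.sample_ids)):
            idx = [int(np.argmin(np.abs(planted - mz))) for mz in bpm.feature_mz]
            rho = spearmanr(bpm.values[row], cohort.log2_abundance[row, idx]).statistic
            assert rho > 0.99

    def test_scale_invariance_through_pipeline(self, pipeline_result):
        cfg, cohort, truth, bpm, _ = pipeline_result
        rec = sd.simulate_recording(
            2.0 ** cohort.log2_abundance[0], truth.feature_mz, cfg,
            rng=1000, sample_id="s", baseline_level=0.05,
        )
        scaled = ScanSeries(
            times=rec.times,
            mz_arrays=rec.mz_arrays,
            intensity_arrays=[i * 3.0 for i in rec.intensity_arrays],
            polarity=rec.polarity,
            sample_id="s_scaled",
        )
        p1, _ = pp.process_sample(rec)
        p2, _ = pp.process_sample(scaled)
        a1 = p1.table["area"].to_numpy()
        a2 = p2.table["area"].to_numpy()
        assert len(a1) == len(a2)
        np.testing.assert_allclose(a1 / a1.sum(), a2 / a2.sum(), rtol=1e-9)
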