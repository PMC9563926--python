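"""Recalibration, gridding, gating, peak picking and normalization."""

import numpy as np
import pytest

import breathflow as bf
from breathflow.errors import (
    CalibrationError,
    NoBreathDetectedError,
    NormalizationError,
)
from breathflow.preprocess import DEFAULT_CALIBRANTS


def _calibrant_spectrum(shift=0.0, slope=1.0):
    """Dense profile with the three water-cluster calibrant peaks."""
    pieces_mz, pieces_int = [], []
    for cal in DEFAULT_CALIBRANTS:
        sigma = cal / 30000.0 / 2.3548
        mz = cal + sigma * np.arange(-8, 9) / 2.0
        pieces_mz.append(mz * slope + shift)
        pieces_int.append(100.0 * np.exp(-0.5 * ((mz - cal) / sigma) ** 2))
    mz = np.concatenate(pieces_mz)
    order = np.argsort(mz)
    return bf.MassSpectrum(mz=mz[order], intensity=np.concatenate(pieces_int)[order])


class TestRecalibration:
    def test_identity(self):
        ref = _calibrant_spectrum()
        session = bf.BreathSession(subject_id="s", scans=[_calibrant_spectrum()])
        model = bf.fit_recalibration(session, ref)
        assert model.slope == pytest.approx(1.0, abs=1e-9)
        assert model.offset == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("shift", [0.002, -0.003, 0.01])
    def test_planted_shift_recovered(self, shift):
        """A +s Da shift fits offset ~ -s with sub-5e-4 Da residuals."""
        ref = _calibrant_spectrum()
        session = bf.BreathSession(
            subject_id="s", scans=[_calibrant_spectrum(shift=shift)]
        )
        model = bf.fit_recalibration(session, ref)
        assert model.offset == pytest.approx(-shift, abs=2e-4)
        assert model.max_residual < 5e-4

    def test_water_trimer_mapped_to_reference(self):
        ref = _calibrant_spectrum()
        session = bf.BreathSession(
            subject_id="s", scans=[_calibrant_spectrum(shift=0.004)]
        )
        model = bf.fit_recalibration(session, ref)
        corrected = model.apply(np.array([bf.WATER_TRIMER_MZ + 0.004]))
        assert corrected[0] == pytest.approx(bf.WATER_TRIMER_MZ, abs=5e-4)

    def test_too_few_calibrants(self):
        ref = _calibrant_spectrum()
        lone = bf.MassSpectrum(
            mz=np.array([300.0]), intensity=np.array([50.0])
        )
        with pytest.raises(CalibrationError, match="calibrant"):
            bf.fit_recalibration(
                bf.BreathSession(subject_id="s", scans=[lone]), ref
            )

    def test_apply_then_inverse_is_identity(self):
        session = bf.BreathSession(subject_id="s", scans=[_calibrant_spectrum()])
        model = bf.CalibrationModel(slope=1.0000004, offset=-0.0021)
        back = bf.apply_recalibration(
            bf.apply_recalibration(session, model), model.inverse()
        )
        np.testing.assert_allclose(
            back.scans[0].mz, session.scans[0].mz, atol=1e-12
        )

    def test_intensities_untouched(self):
        session = bf.BreathSession(subject_id="s", scans=[_calibrant_spectrum()])
        model = bf.CalibrationModel(slope=1.0, offset=0.003)
        out = bf.apply_recalibration(session, model)
        np.testing.assert_array_equal(
            out.scans[0].intensity, session.scans[0].intensity
        )


class TestInterpolation:
    def test_on_grid_unchanged(self):
        grid = bf.FeatureGrid(100.0, 100.01, 0.001)
        spec = bf.MassSpectrum(mz=grid.mz_grid, intensity=np.arange(len(grid), dtype=float))
        np.testing.assert_allclose(
            bf.interpolate_to_grid(spec, grid), np.arange(len(grid)), atol=1e-12
        )

    def test_linear_midpoint(self):
        grid = bf.FeatureGrid(100.0, 100.002, 0.001)
        spec = bf.MassSpectrum(
            mz=np.array([100.000, 100.002]), intensity=np.array([0.0, 10.0])
        )
        assert bf.interpolate_to_grid(spec, grid)[1] == pytest.approx(5.0)

    def test_outside_support_zero(self):
        grid = bf.FeatureGrid(50.0, 60.0, 0.5)
        spec = bf.MassSpectrum(
            mz=np.array([54.0, 55.0]), intensity=np.array([1.0, 2.0])
        )
        out = bf.interpolate_to_grid(spec, grid)
        assert out[0] == 0.0 and out[-1] == 0.0

    def test_gaussian_area_preserved(self, gaussian_spectrum):
        """Resampling to a 2x finer grid keeps the peak area within 1%."""
        native_area = np.trapezoid(
            gaussian_spectrum.intensity, gaussian_spectrum.mz
        )
        grid = bf.FeatureGrid(99.9, 100.1, 0.00025)
        resampled = bf.interpolate_to_grid(gaussian_spectrum, grid)
        area = np.trapezoid(resampled, grid.mz_grid)
        assert area == pytest.approx(native_area, rel=0.01)

    def test_empty_spectrum_rejected(self):
        grid = bf.FeatureGrid(50.0, 60.0, 0.5)
        spec = bf.MassSpectrum(mz=np.array([]), intensity=np.array([]))
        with pytest.raises(ValueError):
            bf.interpolate_to_grid(spec, grid)


def _gate_session(window_max_per_scan):
    """Session whose per-scan water-trimer window maxima are as given."""
    scans = []
    for t, h in enumerate(window_max_per_scan):
        scans.append(
            bf.MassSpectrum(
                mz=np.array([55.0380, 55.0390, 55.0400, 100.0]),
                intensity=np.array([h / 2, h, h / 2, 50.0]),
                scan_time=float(t),
            )
        )
    return bf.BreathSession(subject_id="gate", scans=scans)


class TestGate:
    def test_no_signal_is_error(self):
        with pytest.raises(NoBreathDetectedError):
            bf.select_breath_scans(_gate_session([0.0, 0.0, 0.0]))

    def test_threshold_selects_bursts(self):
        idx = bf.select_breath_scans(_gate_session([1.0, 100.0, 100.0, 2.0, 90.0]))
        assert idx == [1, 2, 4]

    def test_all_above_gate(self):
        idx = bf.select_breath_scans(_gate_session([50.0, 100.0, 60.0]))
        assert idx == [0, 1, 2]

    def test_gate_fraction_monotone(self):
        """Raising the gate fraction never adds a selected scan."""
        session = _gate_session([5.0, 15.0, 40.0, 100.0, 8.0])
        prev = None
        for frac in (0.01, 0.05, 0.1, 0.3, 0.5, 0.9):
            cur = set(bf.select_breath_scans(session, gate_fraction=frac))
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestPeakPicking:
    def test_flat_zero_empty(self):
        grid = bf.FeatureGrid(50.0, 51.0, 0.01)
        peaks = bf.pick_peaks(np.zeros(len(grid)), grid)
        assert len(peaks) == 0

    def test_single_gaussian(self, gaussian_spectrum):
        grid = bf.FeatureGrid(99.9, 100.1, 0.001)
        trace = bf.interpolate_to_grid(gaussian_spectrum, grid)
        peaks = bf.pick_peaks(trace, grid)
        assert len(peaks) == 1
        assert peaks.centroids[0] == pytest.approx(100.0, abs=0.001)
        assert peaks.heights[0] == pytest.approx(10.0, rel=0.01)

    @pytest.mark.parametrize("apex,expected", [(4.9, 0), (5.0, 1), (5.1, 1)])
    def test_height_filter_boundary(self, apex, expected):
        """The 5 counts/s filter is a closed bound: 4.9 out, 5.0 in."""
        grid = bf.FeatureGrid(100.0, 100.02, 0.001)
        trace = apex * np.exp(
            -0.5 * ((grid.mz_grid - 100.01) / 0.002) ** 2
        )
        assert len(bf.pick_peaks(trace, grid, min_height=5.0)) == expected

    def test_plateau_resolves_to_midpoint(self):
        grid = bf.FeatureGrid(100.0, 100.008, 0.001)
        trace = np.array([0.0, 1.0, 8.0, 8.0, 8.0, 1.0, 0.0, 0.0, 0.0])
        peaks = bf.pick_peaks(trace, grid, min_height=5.0)
        assert len(peaks) == 1
        # centroid of the symmetric half-apex region is the plateau middle
        assert peaks.centroids[0] == pytest.approx(100.003, abs=1e-9)

    def test_min_height_monotone(self):
        rng = np.random.default_rng(5)
        grid = bf.FeatureGrid(50.0, 52.0, 0.002)
        trace = np.abs(rng.normal(3.0, 4.0, len(grid)))
        prev = None
        for h in (1.0, 2.0, 5.0, 10.0):
            n = len(bf.pick_peaks(trace, grid, min_height=h))
            if prev is not None:
                assert n <= prev
            prev = n


class TestAveraging:
    def _session_two_scans(self):
        sigma = 100.0 / 30000.0 / 2.3548
        mz = np.arange(99.99, 100.01, 0.0002)
        mk = lambda apex, t: bf.MassSpectrum(
            mz=mz,
            intensity=apex * np.exp(-0.5 * ((mz - 100.0) / sigma) ** 2),
            scan_time=t,
        )
        return bf.BreathSession(subject_id="avg", scans=[mk(4.0, 0.0), mk(8.0, 0.5)])

    def test_mean_of_two_scans(self, narrow_grid):
        session = self._session_two_scans()
        grid = bf.FeatureGrid(99.95, 100.05, 0.0005)
        profile = bf.average_breath_scans(session, [0, 1], grid)
        assert len(profile.feature_mz) == 1
        assert profile.feature_intensity[0] == pytest.approx(6.0, rel=0.01)

    def test_single_scan_equals_picked_peaks(self):
        session = self._session_two_scans()
        grid = bf.FeatureGrid(99.95, 100.05, 0.0005)
        profile = bf.average_breath_scans(session, [1], grid)
        trace = bf.interpolate_to_grid(session.scans[1], grid)
        peaks = bf.pick_peaks(trace, grid)
        np.testing.assert_allclose(profile.feature_mz, peaks.centroids)
        np.testing.assert_allclose(profile.feature_intensity, peaks.heights)

    def test_empty_index_set(self):
        session = self._session_two_scans()
        grid = bf.FeatureGrid(99.95, 100.05, 0.0005)
        with pytest.raises(ValueError):
            bf.average_breath_scans(session, [], grid)

    def test_pick_then_average_mode(self):
        session = self._session_two_scans()
        grid = bf.FeatureGrid(99.95, 100.05, 0.0005)
        profile = bf.average_breath_scans(session, [0, 1], grid, pick_per_scan=True)
        assert len(profile.feature_mz) == 1
        assert profile.feature_intensity[0] == pytest.approx(6.0, rel=0.01)


def _profile(sid, mz, inten):
    mz = np.asarray(mz, float)
    inten = np.asarray(inten, float)
    return bf.SubjectProfile(
        subject_id=sid, feature_mz=mz, feature_intensity=inten, tic=float(inten.sum())
    )


class TestFeatureMatrix:
    def test_close_features_merge(self):
        m = bf.build_feature_matrix(
            [_profile("a", [125.0958], [10.0]), _profile("b", [125.0960], [20.0])]
        )
        assert m.feature_mz.size == 1
        assert 125.0958 <= m.feature_mz[0] <= 125.0960

    def test_distant_features_split(self):
        m = bf.build_feature_matrix(
            [_profile("a", [125.0958], [10.0]), _profile("b", [125.1018], [20.0])]
        )
        assert m.feature_mz.size == 2
        assert m.values[0, 1] == 0.0 and m.values[1, 0] == 0.0

    def test_shared_features_stack(self):
        mzs = [100.0, 150.0, 200.0]
        m = bf.build_feature_matrix(
            [_profile("a", mzs, [1.0, 2.0, 3.0]), _profile("b", mzs, [4.0, 5.0, 6.0])]
        )
        np.testing.assert_allclose(m.values, [[1, 2, 3], [4, 5, 6]])
        np.testing.assert_allclose(m.feature_mz, mzs, atol=1e-12)


class TestNormalizationCascade:
    def _matrix(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1.0, 50.0, (5, 8))
        return bf.IntensityMatrix(
            subject_ids=[f"s{i}" for i in range(5)],
            feature_mz=np.linspace(60, 200, 8),
            values=vals,
            tics=vals.sum(axis=1),
        )

    def test_tic_rows_sum_to_one(self):
        m = self._matrix()
        out = bf.normalize_cascade(m)
        np.testing.assert_allclose(out.tic_values.sum(axis=1), 1.0, atol=1e-9)

    def test_autoscaled_columns(self):
        out = bf.normalize_cascade(self._matrix())
        assert out.state == "autoscaled"
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-9)

    def test_scale_invariance(self):
        """Scaling one subject's raw row by c > 0 leaves its TIC row alone."""
        m1 = self._matrix()
        m2 = self._matrix()
        m2.values[2] *= 7.3
        m2.tics = m2.values.sum(axis=1)
        out1 = bf.normalize_cascade(m1)
        out2 = bf.normalize_cascade(m2)
        np.testing.assert_allclose(out2.tic_values[2], out1.tic_values[2], atol=1e-12)

    def test_identical_subjects_identical_rows(self):
        vals = np.vstack([np.arange(1.0, 9.0)] * 2 + [np.arange(2.0, 10.0)])
        m = bf.IntensityMatrix(
            subject_ids=["a", "b", "c"],
            feature_mz=np.linspace(60, 200, 8),
            values=vals,
            tics=vals.sum(axis=1),
        )
        out = bf.normalize_cascade(m)
        np.testing.assert_allclose(out.values[0], out.values[1], atol=1e-12)

    def test_zero_tic_error(self):
        m = self._matrix()
        m.values[1] = 0.0
        m.tics = m.values.sum(axis=1)
        with pytest.raises(NormalizationError, match="s1"):
            bf.normalize_cascade(m)

    def test_state_order_enforced(self):
        out = bf.normalize_cascade(self._matrix())
        with pytest.raises(NormalizationError):
            bf.normalize_cascade(out)
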