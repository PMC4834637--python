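"""Unit tests for the ROI-series -> FC-vector pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcbiomarker import connectivity as conn


def loop_frame_displacement(motion_mm):
    """Independent loop-based FD oracle."""
    n = motion_mm.shape[0]
    fd = [0.0]
    for t in range(1, n):
        fd.append(sum(abs(motion_mm[t, p] - motion_mm[t - 1, p]) for p in range(6)))
    return np.array(fd)


class TestFrameDisplacement:
    def test_constant_motion_is_zero(self):
        motion = np.ones((20, 6)) * 0.3
        assert np.all(conn.frame_displacement(motion) == 0)

    def test_simultaneous_unit_jumps_sum(self):
        motion = np.zeros((10, 6))
        motion[5:, :] += 0.1  # each of 6 parameters jumps by +0.1 mm
        fd = conn.frame_displacement(motion, rotation_radius_mm=None)
        assert fd[5] == pytest.approx(0.6)
        assert np.all(np.delete(fd, 5) == 0)

    def test_matches_loop_oracle_on_random_series(self, rng):
        motion = rng.normal(0, 0.2, size=(50, 6))
        fd = conn.frame_displacement(motion, rotation_radius_mm=None)
        np.testing.assert_allclose(fd, loop_frame_displacement(motion), atol=1e-12)

    def test_rotations_scaled_to_arc_length(self, rng):
        motion = np.zeros((3, 6))
        motion[1, 3] = 0.01  # radians
        fd = conn.frame_displacement(motion, rotation_radius_mm=50.0)
        assert fd[1] == pytest.approx(0.5)
        assert fd[2] == pytest.approx(0.5)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            conn.frame_displacement(np.zeros((10, 5)))


class TestMeanRelativeDisplacement:
    def test_constant_series_zero(self):
        assert np.all(conn.mean_relative_displacement(np.ones((30, 6))) == 0)

    def test_linear_ramp_recovers_slope(self):
        motion = np.zeros((101, 6))
        motion[:, 2] = 0.01 * np.arange(101)
        mrd = conn.mean_relative_displacement(motion, rotation_radius_mm=None)
        assert mrd[2] == pytest.approx(0.01)
        assert np.all(np.delete(mrd, 2) == 0)

    def test_matches_loop_oracle(self, rng):
        motion = rng.normal(size=(40, 6))
        expected = np.abs(np.diff(motion, axis=0)).mean(axis=0)
        np.testing.assert_allclose(
            conn.mean_relative_displacement(motion, rotation_radius_mm=None), expected
        )


class TestScrubMask:
    def test_all_below_threshold_retained(self):
        fd = np.full(50, 0.3)
        mask = conn.scrub_mask(fd)
        assert mask.all()

    def test_single_exceedance_removes_four_frames(self):
        fd = np.zeros(100)
        fd[10] = 0.7
        mask = conn.scrub_mask(fd, threshold=0.5)
        assert not mask[[9, 10, 11, 12]].any()
        assert mask.sum() == 96

    def test_overlapping_windows_are_unioned(self):
        fd = np.zeros(20)
        fd[5] = 1.0
        fd[7] = 1.0
        mask = conn.scrub_mask(fd)
        removed = set(np.flatnonzero(~mask).tolist())
        assert removed == {4, 5, 6, 7} | {6, 7, 8, 9}

    @given(st.lists(st.floats(0, 2), min_size=5, max_size=60), st.floats(0.1, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_lower_threshold_never_retains_more(self, fd_values, threshold):
        fd = np.array(fd_values)
        high = conn.scrub_mask(fd, threshold=threshold)
        low = conn.scrub_mask(fd, threshold=threshold / 2)
        assert low.sum() <= high.sum()


class TestBandpass:
    def test_dc_removed(self):
        x = np.full(512, 7.0)
        out = conn.bandpass(x, tr=2.0)
        assert np.abs(out.mean()) < 1e-6 * 7.0

    def test_passband_sinusoid_preserved(self):
        t = np.arange(512) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = conn.bandpass(x, tr=2.0)
        amp_in = np.abs(np.fft.rfft(x)).max()
        amp_out = np.abs(np.fft.rfft(out)).max()
        assert amp_out == pytest.approx(amp_in, rel=0.10)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(512) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = conn.bandpass(x, tr=2.0)
        assert np.abs(np.fft.rfft(out)).max() <= 0.1 * np.abs(np.fft.rfft(x)).max()

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError):
            conn.bandpass(np.zeros(64), tr=2.0, low=0.01, high=0.3)  # 0.3 > Nyquist


class TestNuisanceRegress:
    def test_regressor_itself_is_annihilated(self, rng):
        reg = rng.standard_normal((128, 1))
        out = conn.nuisance_regress(reg.copy(), reg, tr=2.0)
        assert np.abs(out).max() < 1e-8 * np.abs(reg).max() + 1e-10

    def test_residuals_orthogonal_to_filtered_regressors(self, rng):
        series = rng.standard_normal((128, 4))
        regs = rng.standard_normal((128, 5))
        resid = conn.nuisance_regress(series, regs, tr=2.0)
        filt = conn.bandpass(regs, tr=2.0)
        for j in range(4):
            for k in range(5):
                assert abs(np.corrcoef(resid[:, j], filt[:, k])[0, 1]) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        series = rng.standard_normal((100, 3))
        regs = rng.standard_normal((100, 4))
        resid = conn.nuisance_regress(series, regs, tr=2.0)
        y = conn.bandpass(series, tr=2.0)
        x = np.column_stack([np.ones(100), conn.bandpass(regs, tr=2.0)])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(resid, y - x @ beta, atol=1e-9)


class TestFcVector:
    def test_length_law_for_140_regions(self):
        assert conn.n_fc_pairs(140) == 9730
        assert len(conn.fc_index_pairs(140)) == 9730

    def test_duplicated_region_has_unit_correlation(self, rng):
        a = rng.standard_normal(40)
        series = np.column_stack([a, a, rng.standard_normal(40)])
        vec = conn.fc_vector(series)
        # position 0 pairs regions (1, 0)
        assert vec.index_map[0] == (1, 0)
        assert vec.values[0] == pytest.approx(1.0)

    def test_three_region_toy_matches_hand_formula(self):
        series = np.array(
            [
                [1.0, 2.0, 0.5],
                [2.0, 1.0, 1.5],
                [3.0, 4.0, 0.0],
                [4.0, 3.0, 2.0],
                [5.0, 6.0, 1.0],
                [6.0, 5.0, 3.0],
            ]
        )
        vec = conn.fc_vector(series)

        def pearson(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return float(a @ b / np.sqrt((a @ a) * (b @ b)))

        expected = [
            pearson(series[:, 1], series[:, 0]),
            pearson(series[:, 2], series[:, 0]),
            pearson(series[:, 2], series[:, 1]),
        ]
        np.testing.assert_allclose(vec.values, expected, atol=1e-12)

    def test_full_mask_equals_textbook_lower_triangle(self, rng):
        series = rng.standard_normal((60, 8))
        vec = conn.fc_vector(series, np.ones(60, dtype=bool))
        full = np.corrcoef(series, rowvar=False)
        rows, cols = np.tril_indices(8, k=-1)
        np.testing.assert_allclose(vec.values, full[rows, cols], atol=1e-12)

    def test_masked_frames_excluded_from_correlation(self, rng):
        series = rng.standard_normal((50, 3))
        mask = np.ones(50, dtype=bool)
        mask[10:20] = False
        vec = conn.fc_vector(series, mask)
        expected = np.corrcoef(series[mask], rowvar=False)[1, 0]
        assert vec.values[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_region_stored_as_zero_with_warning(self):
        series = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0) ** 2])
        with pytest.warns(UserWarning):
            vec = conn.fc_vector(series)
        assert vec.values[0] == 0.0  # pair (1, 0) involves the constant region


class TestProcessSubject:
    def test_end_to_end_on_synthetic_subject(self):
        from fcbiomarker import synthetic

        sub = synthetic.generate_timeseries(
            200, 5, motion=synthetic.MotionSpec(200, spike_frames=(50,), spike_magnitude=1.0),
            seed=1,
        )
        ts = conn.RoiTimeSeries(
            data=sub["data"], tr=2.0, motion=sub["motion"], tissue_signals=sub["tissue_signals"]
        )
        vec, qm = conn.process_subject(ts)
        assert len(vec.values) == conn.n_fc_pairs(5)
        assert np.all(np.abs(vec.values) <= 1)
        assert qm.fd[0] == 0
        assert qm.retained_fraction < 1.0  # the spike got scrubbed

    def test_no_spikes_retains_all_frames(self):
        from fcbiomarker import synthetic

        sub = synthetic.generate_timeseries(100, 4, seed=2)
        ts = conn.RoiTimeSeries(
            data=sub["data"], tr=2.0, motion=sub["motion"], tissue_signals=sub["tissue_signals"]
        )
        _, qm = conn.process_subject(ts)
        assert qm.retained_fraction == 1.0
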