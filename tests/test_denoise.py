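import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spineprint as sp
from spineprint.denoise import VoxelBlock


class TestCardiacPhase:
    def test_linear_ramp_between_peaks(self):
        phase = sp.cardiac_phase([0.0, 1.0, 2.0], [0.5, 1.0, 1.75])
        assert np.allclose(phase, [np.pi, 0.0, 1.5 * np.pi])

    def test_uneven_interval_interpolation(self):
        assert np.isclose(sp.cardiac_phase([0.0, 2.0], [0.5])[0], np.pi / 2)

    def test_extrapolation_uses_nearest_interval(self):
        # before the first peak: first interval, periodic; after: last interval
        phase = sp.cardiac_phase([1.0, 2.0, 4.0], [0.5, 5.0])
        assert np.isclose(phase[0], np.pi)  # half an interval before peak 1
        assert np.isclose(phase[1], np.pi)  # half a (2 s) interval after peak 3

    def test_range_and_errors(self, rng):
        peaks = np.cumsum(rng.uniform(0.7, 1.3, 50))
        t = rng.uniform(peaks[0], peaks[-1], 200)
        phase = sp.cardiac_phase(peaks, t)
        assert np.all((phase >= 0) & (phase < 2 * np.pi))
        with pytest.raises(ValueError):
            sp.cardiac_phase([1.0], [0.5])


class TestRespiratoryPhase:
    def test_sinusoid_extremes(self):
        t = np.arange(0, 40, 0.02)
        w = np.sin(2 * np.pi * 0.25 * t)
        phase = sp.respiratory_phase(w, t)
        # at maximum amplitude the rising->falling transition has |phase| ~ pi
        assert abs(phase[np.argmax(w)]) > 0.95 * np.pi
        # phase stays in (-pi, pi]
        assert np.all((phase > -np.pi) & (phase <= np.pi))

    def test_median_amplitude_rising_gives_half_pi(self):
        t = np.arange(0, 40, 0.02)
        w = np.sin(2 * np.pi * 0.25 * t)
        phase = sp.respiratory_phase(w, t)
        rising_at_zero = (np.abs(w) < 0.01) & (np.gradient(w) > 0)
        assert np.allclose(phase[rising_at_zero], np.pi / 2, atol=0.1)

    def test_constant_waveform_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sp.respiratory_phase(np.ones(100), np.arange(100.0))


class TestRetroicorDesign:
    def test_standard_orders_give_32_columns(self, rng):
        pc = rng.uniform(0, 2 * np.pi, 200)
        pr = rng.uniform(-np.pi, np.pi, 200)
        design = sp.retroicor_design(pc, pr, 4, 4, 2)
        assert design.n_regressors == 32
        assert len(design.column_names) == 32

    def test_single_fundamental(self, rng):
        pc = rng.uniform(0, 2 * np.pi, 50)
        design = sp.retroicor_design(pc, np.zeros(50), 1, 0, 0)
        assert design.n_regressors == 2
        assert np.allclose(design.matrix[:, 0], np.sin(pc))
        assert np.allclose(design.matrix[:, 1], np.cos(pc))

    def test_zero_respiratory_phase_flags_zero_columns(self, rng):
        pc = rng.uniform(0, 2 * np.pi, 100)
        with pytest.warns(UserWarning, match="identically zero"):
            design = sp.retroicor_design(pc, np.zeros(100), 4, 4, 2)
        resp_sin = [i for i, n in enumerate(design.column_names)
                    if n.startswith("resp_sin")]
        resp_cos = [i for i, n in enumerate(design.column_names)
                    if n.startswith("resp_cos")]
        assert np.all(design.matrix[:, resp_sin] == 0)
        assert np.all(design.matrix[:, resp_cos] == 1)

    @settings(max_examples=40, deadline=None)
    @given(
        c=st.integers(0, 5), r=st.integers(0, 5), i=st.integers(0, 3),
        seed=st.integers(0, 10_000),
    )
    def test_column_count_closed_form(self, c, r, i, seed):
        """Column count is 2c + 2r + 4i^2 for any non-negative orders."""
        g = np.random.default_rng(seed)
        pc = g.uniform(0, 2 * np.pi, 30)
        pr = g.uniform(-np.pi, np.pi, 30)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = sp.retroicor_design(pc, pr, c, r, i)
        assert design.n_regressors == 2 * c + 2 * r + 4 * i**2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            sp.retroicor_design(np.zeros(10), np.zeros(11), 1, 1, 0)


class TestCsfRegressor:
    def test_dominant_variance_voxel_selected(self, rng):
        quiet = 0.01 * rng.standard_normal((9, 100))
        loud = rng.standard_normal((1, 100))
        block = VoxelBlock(np.vstack([quiet, loud]), tr=2.0)
        out = sp.csf_regressor(block, fraction=0.10)
        assert np.allclose(out, loud[0])

    def test_fraction_one_is_plain_mean(self, rng):
        data = rng.standard_normal((7, 60))
        out = sp.csf_regressor(VoxelBlock(data, tr=2.0), fraction=1.0)
        assert np.allclose(out, data.mean(axis=0))

    def test_matches_exhaustive_variance_sort(self, rng):
        data = rng.standard_normal((20, 80))
        out = sp.csf_regressor(VoxelBlock(data, tr=2.0), fraction=0.10)
        top2 = np.argsort(data.var(axis=1, ddof=1))[-2:]
        assert np.allclose(out, data[np.sort(top2)].mean(axis=0))


class TestCleanTimeseries:
    def test_full_band_is_mean_centering(self, rng):
        x = rng.standard_normal((4, 120))
        tr = 2.0
        out = sp.clean_timeseries(x, band=(0.0, 1 / (2 * tr)), tr=tr)
        assert np.allclose(out, x - x.mean(axis=1, keepdims=True), atol=1e-10)

    def test_stopband_sinusoid_suppressed(self):
        t = np.arange(250) * 2.08
        x = np.sin(2 * np.pi * 0.2 * t)[None, :]
        out = sp.clean_timeseries(x, band=(0.01, 0.13), tr=2.08)
        assert (out**2).sum() / (x**2).sum() < 1e-3

    def test_passband_sinusoid_preserved(self):
        t = np.arange(250) * 2.08
        x = np.sin(2 * np.pi * 0.05 * t)[None, :]
        out = sp.clean_timeseries(x, band=(0.01, 0.13), tr=2.08)
        assert (out**2).sum() / (x**2).sum() > 0.95

    def test_idempotent_and_orthogonal_to_confounds(self, rng):
        x = rng.standard_normal((6, 200))
        conf = rng.standard_normal((200, 5))
        out = sp.clean_timeseries(x, confounds=conf, tr=2.0)
        again = sp.clean_timeseries(out, confounds=conf, tr=2.0)
        assert np.abs(out - again).max() < 1e-10
        assert np.abs(out @ conf).max() < 1e-8

    def test_rank_deficient_confounds_tolerated(self, rng):
        x = rng.standard_normal((2, 150))
        c = rng.standard_normal((150, 3))
        conf = np.hstack([c, c[:, :1]])  # duplicated column
        out = sp.clean_timeseries(x, confounds=conf, tr=2.0)
        assert np.abs(out @ conf).max() < 1e-8

    def test_overcomplete_basis_rejected(self, rng):
        with pytest.raises(ValueError, match="nuisance space"):
            sp.clean_timeseries(
                rng.standard_normal((1, 40)),
                confounds=rng.standard_normal((40, 40)),
                tr=2.0,
            )

    def test_transformer_in_sklearn_pipeline(self, rng):
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([("clean", sp.TimeSeriesCleaner(tr=2.0))])
        x = rng.standard_normal((3, 100))
        out = pipe.fit_transform(x)
        assert out.shape == x.shape


class TestTsnr:
    def test_direct_ratio(self, rng):
        x = 100 + 5 * rng.standard_normal((1, 5000))
        block = VoxelBlock(x, tr=2.0)
        assert np.isclose(sp.tsnr(block)[0], x.mean() / x.std(ddof=1))
        assert abs(sp.tsnr(block)[0] - 20) < 1

    def test_zero_mean_noise_near_zero(self, rng):
        block = VoxelBlock(rng.standard_normal((10, 2000)), tr=2.0)
        assert np.abs(sp.tsnr(block)).max() < 0.2

    def test_constant_voxel_flagged_infinite(self):
        block = VoxelBlock(np.vstack([np.ones(10), np.arange(10.0)]), tr=2.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = sp.tsnr(block)
        assert np.isinf(out[0])


class TestRobustParcelMean:
    def test_identical_voxels_pass_through(self, spinal_scheme_3, rng):
        block, truth = sp.generate_voxel_block(
            spinal_scheme_3, voxels_per_region=8, seed=0, noise_sd=0.0
        )
        ts = sp.robust_parcel_mean(block, spinal_scheme_3)
        assert np.allclose(ts.data, truth)

    def test_single_outlier_excluded(self):
        scheme = sp.build_spinal_scheme(["C4"])
        data = np.ones((21 * 14, 30))
        labels = [n for n in scheme.names for _ in range(21)]
        data[0, 5] = 1e6  # one voxel of the first region spikes once
        ts = sp.robust_parcel_mean(VoxelBlock(data, tr=2.0, labels=labels), scheme)
        assert ts.data[0, 5] == pytest.approx(1.0)

    def test_small_region_plain_mean_fallback(self):
        scheme = sp.build_spinal_scheme(["C4"])
        rng = np.random.default_rng(3)
        data = rng.standard_normal((14, 40))  # one voxel per region
        ts = sp.robust_parcel_mean(
            VoxelBlock(data, tr=2.0, labels=list(scheme.names)), scheme
        )
        assert np.allclose(ts.data, data)

    def test_output_bounded_by_voxel_envelope(self, spinal_scheme_3):
        block, _ = sp.generate_voxel_block(
            spinal_scheme_3, voxels_per_region=9, seed=2, noise_sd=1.0
        )
        ts = sp.robust_parcel_mean(block, spinal_scheme_3)
        labels = np.asarray(block.labels)
        for i, name in enumerate(spinal_scheme_3.names):
            vox = block.data[labels == name]
            assert np.all(ts.data[i] >= vox.min(axis=0) - 1e-12)
            assert np.all(ts.data[i] <= vox.max(axis=0) + 1e-12)

    def test_missing_region_reported(self, spinal_scheme_3):
        block, _ = sp.generate_voxel_block(
            spinal_scheme_3, voxels_per_region=2, seed=1
        )
        wrong = sp.build_spinal_scheme(["C4", "C5", "C6", "C7"])
        with pytest.raises(ValueError, match="zero voxels"):
            sp.robust_parcel_mean(block, wrong)
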