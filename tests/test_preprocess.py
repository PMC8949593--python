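"""Preprocessing operators: SG derivative, SNV, Whittaker baseline,
peak-area normalisation, region selection, mean-centering and chains."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import amorphquant as aq
from amorphquant.preprocess import ChainStepError, PreprocessChain, _uniform_segments


def _raman(y, axis=None):
    axis = np.arange(100.0, 100.0 + len(y)) if axis is None else axis
    return aq.Spectrum(axis=axis, intensities=np.asarray(y, float),
                       modality=aq.Modality.RAMAN)


class TestSavGolDerivative:
    def test_second_derivative_of_line_is_zero(self):
        axis = np.arange(100.0, 500.0, 4.0)
        s = _raman(5.0 * axis, axis=axis)
        out = aq.savgol_derivative(s, aq.SavGolParams())
        assert np.all(np.abs(out.intensities) < 1e-9)

    def test_reproduces_quadratic_exactly(self):
        # 3 i^2 on a unit-step grid: 2nd derivative per step is exactly 6
        i = np.arange(200.0)
        s = _raman(3.0 * i**2, axis=100.0 + i)
        out = aq.savgol_derivative(s, aq.SavGolParams(window=21, polyorder=2,
                                                      deriv_order=2))
        np.testing.assert_allclose(out.intensities, 6.0, rtol=0, atol=1e-8)
        assert out.n_points == 200 - 20  # (window-1)/2 trimmed each end

    def test_matches_pointwise_polyfit_oracle(self, rng):
        y = rng.normal(size=200)
        axis = np.arange(100.0, 300.0)
        s = _raman(y, axis=axis)
        p = aq.SavGolParams(window=11, polyorder=3, deriv_order=2)
        out = aq.savgol_derivative(s, p)
        half = (p.window - 1) // 2
        for j in range(0, out.n_points, 17):
            center = j + half
            window = np.arange(center - half, center + half + 1)
            coeffs = np.polynomial.polynomial.polyfit(
                window - center, y[window], p.polyorder)
            # 2nd derivative of the local polynomial at its center
            expected = 2.0 * coeffs[2]
            assert out.intensities[j] == pytest.approx(expected, abs=1e-8)

    def test_non_uniform_axis_instructs_resampling(self, rng):
        axis = np.sort(rng.uniform(100.0, 2000.0, size=50))
        s = _raman(rng.normal(size=50), axis=axis)
        with pytest.raises(aq.DegenerateInputError, match="resample"):
            aq.savgol_derivative(s, aq.SavGolParams())

    def test_piecewise_uniform_axis_processed_per_segment(self):
        axis = np.concatenate([np.arange(100.0, 500.0, 4.0),
                               np.arange(800.0, 1200.0, 4.0)])
        s = _raman(2.0 * axis, axis=axis)
        out = aq.savgol_derivative(s, aq.SavGolParams())
        assert np.all(np.abs(out.intensities) < 1e-9)
        assert out.n_points == 2 * (100 - 20)

    def test_segment_detection_drops_the_gap_step(self):
        axis = np.concatenate([np.arange(0.0, 80.0, 8.0),
                               np.arange(400.0, 480.0, 8.0)])
        segs = _uniform_segments(axis)
        assert [axis[s].size for s in segs] == [10, 10]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            aq.SavGolParams(window=4)
        with pytest.raises(ValueError):
            aq.SavGolParams(window=5, polyorder=5)
        with pytest.raises(ValueError):
            aq.SavGolParams(window=5, polyorder=2, deriv_order=3)


class TestSnv:
    def test_output_has_zero_mean_unit_sd(self, rng):
        out = aq.snv(_raman(rng.normal(2.0, 3.0, size=100)))
        assert abs(out.intensities.mean()) < 1e-12
        assert np.std(out.intensities, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_spectrum_is_degenerate(self):
        with pytest.raises(aq.DegenerateInputError, match="constant"):
            aq.snv(_raman(np.full(50, 3.3)))

    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        y = rng.normal(size=64)
        base = aq.snv(_raman(y)).intensities
        scaled = aq.snv(_raman(a * y + b)).intensities
        np.testing.assert_allclose(scaled, base, rtol=0, atol=1e-9)

    def test_removes_simulator_multiplicative_scatter(self):
        """SNV recovers the noise-free processed spectrum under pure scatter."""
        clean_cfg = aq.SimulationConfig(modality=aq.Modality.RAMAN,
                                        noise=aq.NoiseModel.noiseless(), seed=3)
        scatter_cfg = aq.SimulationConfig(
            modality=aq.Modality.RAMAN,
            noise=aq.NoiseModel(0.0, 0.5, 0.0, 0.0, 0.0, 0.0), seed=3)
        comp = aq.MixtureComposition(10.0, 10.0, 77.0, 3.0)
        clean = aq.simulate_mixture(comp, clean_cfg, rng=clean_cfg.rng())
        distorted = aq.simulate_mixture(comp, scatter_cfg, rng=scatter_cfg.rng())
        np.testing.assert_allclose(aq.snv(distorted).intensities,
                                   aq.snv(clean).intensities, rtol=0, atol=1e-9)


class TestWhittakerBaseline:
    def test_zero_spectrum_is_fixed_point(self):
        baseline, corrected = aq.whittaker_baseline(_raman(np.zeros(50)))
        assert np.all(baseline.intensities == 0.0)
        assert np.all(corrected.intensities == 0.0)

    def test_recovers_linear_baseline_under_positive_peaks(self):
        axis = np.arange(100.0, 1100.0)
        truth = 2.0 + 0.001 * axis
        y = truth.copy()
        for center in (250.0, 400.0, 550.0, 700.0, 850.0):
            y += 5.0 * np.exp(-0.5 * ((axis - center) / 8.0) ** 2)
        baseline, _ = aq.whittaker_baseline(_raman(y, axis=axis),
                                            aq.WhittakerParams())
        rel_err = np.abs(baseline.intensities - truth) / truth
        assert np.mean(rel_err < 0.02) >= 0.95

    def test_banded_solve_matches_dense_oracle(self, rng):
        n = 50
        y = rng.normal(size=n).cumsum()
        s = _raman(y)
        params = aq.WhittakerParams(lam=500.0, p=0.01, max_iter=1)
        baseline, _ = aq.whittaker_baseline(s, params)
        # dense normal equations with the same all-ones starting weights
        D = np.diff(np.eye(n), n=2, axis=0)
        z = np.linalg.solve(np.eye(n) + params.lam * D.T @ D, y)
        assert np.max(np.abs(baseline.intensities - z)) < 1e-8

    def test_roughness_non_increasing_in_lambda(self, rng):
        y = np.abs(rng.normal(size=300)).cumsum()
        s = _raman(y)
        roughness = []
        for lam in (1e1, 1e3, 1e5, 1e7):
            z, _ = aq.whittaker_baseline(s, aq.WhittakerParams(lam=lam, max_iter=1))
            roughness.append(np.sum(np.diff(z.intensities, n=2) ** 2))
        assert np.all(np.diff(roughness) <= 1e-12)

    def test_too_short_input_rejected(self):
        with pytest.raises(aq.DegenerateInputError, match=">= 4"):
            aq.whittaker_baseline(_raman([1.0, 2.0, 3.0]))


class TestNormalizeToPeakArea:
    def test_window_area_is_one_after_normalisation(self, rng):
        axis = np.arange(1000.0, 1701.0)
        y = np.abs(rng.normal(size=axis.size)) + 0.5
        out = aq.normalize_to_peak_area(_raman(y, axis=axis))
        mask = (out.axis >= 1599.0) & (out.axis <= 1629.0)
        area = np.trapezoid(out.intensities[mask], out.axis[mask])
        assert area == pytest.approx(1.0, abs=1e-9)

    @given(c=st.floats(0.1, 50.0))
    def test_positive_scale_invariance(self, c):
        axis = np.arange(1500.0, 1701.0)
        y = 1.0 + np.exp(-0.5 * ((axis - 1614.0) / 6.0) ** 2)
        base = aq.normalize_to_peak_area(_raman(y, axis=axis)).intensities
        scaled = aq.normalize_to_peak_area(_raman(c * y, axis=axis)).intensities
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_divisor_matches_independent_quadrature(self):
        axis = np.arange(1500.0, 1701.0)
        fwhm = 10.0
        y = np.exp(-4 * np.log(2) * (axis - 1614.0) ** 2 / fwhm**2)
        out = aq.normalize_to_peak_area(_raman(y, axis=axis))
        divisor = y[100] / out.intensities[100]  # same point before/after
        mask = (axis >= 1599.0) & (axis <= 1629.0)
        xs, ys = axis[mask], y[mask]
        manual = sum((ys[i] + ys[i + 1]) / 2.0 * (xs[i + 1] - xs[i])
                     for i in range(len(xs) - 1))
        assert divisor == pytest.approx(manual, rel=1e-12)

    def test_zero_area_window_names_window(self):
        axis = np.arange(1500.0, 1701.0)
        with pytest.raises(aq.DegenerateInputError, match=r"\[1599, 1629\]"):
            aq.normalize_to_peak_area(_raman(np.zeros(axis.size), axis=axis))

    def test_removes_simulator_multiplicative_scatter(self):
        clean_cfg = aq.SimulationConfig(modality=aq.Modality.RAMAN,
                                        noise=aq.NoiseModel.noiseless(), seed=5)
        scatter_cfg = aq.SimulationConfig(
            modality=aq.Modality.RAMAN,
            noise=aq.NoiseModel(0.0, 0.5, 0.0, 0.0, 0.0, 0.0), seed=5)
        comp = aq.MixtureComposition(16.0, 4.0, 77.0, 3.0)
        clean = aq.simulate_mixture(comp, clean_cfg, rng=clean_cfg.rng())
        distorted = aq.simulate_mixture(comp, scatter_cfg, rng=scatter_cfg.rng())
        np.testing.assert_allclose(
            aq.normalize_to_peak_area(distorted).intensities,
            aq.normalize_to_peak_area(clean).intensities, rtol=0, atol=1e-9)


class TestSelectRegion:
    def test_nir_keep_exclude_enumeration_on_8cm_grid(self):
        axis = np.arange(3600.0, 12500.0 + 1e-6, 8.0)
        s = aq.Spectrum(axis=axis, intensities=np.arange(axis.size, dtype=float),
                        modality=aq.Modality.NIR)
        out = aq.select_region(s, aq.RegionSpec(keep=((4000.0, 6200.0),),
                                                exclude=((4800.0, 5200.0),)))
        # independent enumeration of the arithmetic grid under closed-interval rules
        expected = [w for w in axis
                    if 4000.0 <= w <= 6200.0 and not (4800.0 <= w <= 5200.0)]
        np.testing.assert_array_equal(out.axis, expected)
        assert out.axis[0] == 4000.0 and out.axis[-1] == 6200.0
        gap = np.flatnonzero(np.diff(out.axis) > 8.0)
        assert out.axis[gap[0]] == 4792.0 and out.axis[gap[0] + 1] == 5208.0

    def test_raman_unit_grid_closed_interval_count(self):
        axis = np.arange(100.0, 2000.0 + 1e-6, 1.0)
        s = _raman(np.zeros(axis.size), axis=axis)
        out = aq.select_region(s, aq.RegionSpec(keep=((1000.0, 1700.0),)))
        assert out.n_points == 701

    def test_exclusion_covering_keep_is_error(self):
        s = _raman(np.zeros(100))
        with pytest.raises(aq.DegenerateInputError, match="every point"):
            aq.select_region(s, aq.RegionSpec(keep=((100.0, 199.0),),
                                              exclude=((0.0, 500.0),)))

    def test_interval_validation(self):
        with pytest.raises(ValueError, match="lower > upper"):
            aq.RegionSpec(keep=((200.0, 100.0),))


class TestMeanCenter:
    def test_column_means_are_zero_and_state_reusable(self, rng):
        axis = np.arange(100.0, 150.0)
        sset = aq.SpectrumSet([
            aq.Spectrum(axis=axis, intensities=rng.normal(size=50),
                        modality=aq.Modality.RAMAN, sample_id=f"s{i}")
            for i in range(6)])
        centered, means = aq.mean_center(sset)
        np.testing.assert_allclose(centered.intensity_matrix().mean(axis=0),
                                   0.0, atol=1e-12)
        new = sset.spectra[0]
        roundtrip = (new.intensities - means) + means
        np.testing.assert_allclose(roundtrip, new.intensities, rtol=0, atol=1e-12)

    def test_matches_per_column_loop_oracle(self, rng):
        X = rng.normal(size=(5, 30))
        axis = np.arange(100.0, 130.0)
        sset = aq.SpectrumSet([
            aq.Spectrum(axis=axis, intensities=row, modality=aq.Modality.RAMAN,
                        sample_id=f"s{i}") for i, row in enumerate(X)])
        centered, means = aq.mean_center(sset)
        for j in range(30):
            col_mean = sum(X[i, j] for i in range(5)) / 5.0
            assert means[j] == pytest.approx(col_mean, abs=1e-15)
            for i in range(5):
                assert centered.spectra[i].intensities[j] == pytest.approx(
                    X[i, j] - col_mean, abs=1e-12)


class TestApplyChain:
    def test_nir_preset_yields_zero_column_means(self, nir_cfg):
        cal, _, _ = aq.generate_calibration_design(nir_cfg)
        processed, state = aq.apply_chain(cal, aq.nir_default_chain())
        np.testing.assert_allclose(processed.intensity_matrix().mean(axis=0),
                                   0.0, atol=1e-12)
        assert state.column_means is not None

    def test_raman_preset_runs_and_preserves_sample_count(self, raman_cfg):
        cal, _, _ = aq.generate_calibration_design(raman_cfg)
        processed, state = aq.apply_chain(cal, aq.raman_default_chain())
        assert len(processed) == len(cal)
        assert processed.axis[0] >= 1000.0 and processed.axis[-1] <= 1700.0

    def test_empty_chain_is_identity(self, rng):
        axis = np.arange(100.0, 150.0)
        sset = aq.SpectrumSet([
            aq.Spectrum(axis=axis, intensities=rng.normal(size=50),
                        modality=aq.Modality.RAMAN, sample_id=f"s{i}")
            for i in range(3)])
        chain = PreprocessChain(steps=(), modality=aq.Modality.RAMAN)
        out, _ = aq.apply_chain(sset, chain)
        np.testing.assert_array_equal(out.intensity_matrix(),
                                      sset.intensity_matrix())

    def test_frozen_state_is_reused_not_refit(self, nir_cfg):
        cal, val, _ = aq.generate_calibration_design(nir_cfg)
        _, state = aq.apply_chain(cal, aq.nir_default_chain())
        processed_val, _ = aq.apply_chain(val, aq.nir_default_chain(), state=state)
        # reapplying per-spectrum steps and subtracting the STORED means must
        # reproduce the chain output exactly (no refit on validation data)
        per_spectrum = PreprocessChain(
            steps=aq.nir_default_chain().steps[:-1], modality=aq.Modality.NIR)
        manual, _ = aq.apply_chain(val, per_spectrum)
        np.testing.assert_array_equal(
            processed_val.intensity_matrix(),
            manual.intensity_matrix() - state.column_means)

    def test_step_errors_are_annotated_with_index(self):
        s = _raman(np.full(50, 2.0))
        chain = PreprocessChain(steps=(("snv", None),), modality=aq.Modality.RAMAN)
        with pytest.raises(ChainStepError, match=r"step 0 \(snv\)"):
            aq.apply_chain(aq.SpectrumSet([s, s.with_data()]), chain)

    def test_at_most_one_normalization_step(self):
        with pytest.raises(ValueError, match="one normalization"):
            PreprocessChain(steps=(("snv", None), ("normalize_peak_area", None)),
                            modality=aq.Modality.RAMAN)

    def test_water_exclusion_improves_nir_rmsecv_at_default_noise(self):
        """The moisture region carries sample-to-sample humidity noise, so the
        documented 4800-5200 cm^-1 exclusion must lower cross-validated error."""
        from amorphquant.pls import loocv
        included = PreprocessChain(steps=(
            ("select_region", aq.RegionSpec(keep=((4000.0, 6200.0),))),
            ("savgol", aq.SavGolParams()), ("snv", None), ("mean_center", None)),
            modality=aq.Modality.NIR)
        excl_rmsecv, incl_rmsecv = [], []
        for seed in (1, 2, 3, 4, 5):
            cfg = aq.SimulationConfig(modality=aq.Modality.NIR, seed=seed)
            cal, _, _ = aq.generate_calibration_design(
                cfg, rng=np.random.default_rng(seed))
            for chain, acc in ((aq.nir_default_chain(), excl_rmsecv),
                               (included, incl_rmsecv)):
                proc, _ = aq.apply_chain(cal, chain)
                cv = loocv(proc.intensity_matrix(), cal.y_vector(), 6)
                acc.append(np.nanmin(cv.rmsecv_by_nlv))
        assert np.mean(excl_rmsecv) < np.mean(incl_rmsecv)
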