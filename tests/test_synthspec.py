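"""Forward-model tests: calibration laws, spectral composition, noise model."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optodeml import (
    Band,
    SceneSpec,
    SpectralModelParams,
    WavelengthGrid,
    boltzmann_fraction,
    emit_spectrum,
    generate_calibration_cube,
    generate_calibration_set,
    generate_gradient_scene,
    stern_volmer_intensity,
)
from optodeml.synthspec import emit_components, imbalanced_counts


class TestWavelengthGrid:
    def test_default_grid_matches_camera_axis(self, grid):
        v = grid.values
        assert len(grid) == 144
        assert v[0] == 470.0
        assert v[-1] == 899.0
        assert np.allclose(np.diff(v), 3.0)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            WavelengthGrid(step=0)
        with pytest.raises(ValueError):
            WavelengthGrid(start=900, stop=470)


class TestBoltzmann:
    def test_midpoint_and_hand_value(self):
        assert boltzmann_fraction(7.0, 7.0, 1.0) == pytest.approx(0.5)
        # one pH unit above the pKa at unit slope: 1/(1+10^-1) = 10/11
        assert boltzmann_fraction(8.0, 7.0, 1.0) == pytest.approx(10 / 11)

    def test_asymptotes(self):
        assert boltzmann_fraction(-50.0, 7.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert boltzmann_fraction(60.0, 7.0, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_fraction(7.0, 7.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        ph=st.floats(-2, 16),
        pka=st.floats(3, 11),
        slope=st.floats(0.2, 3),
    )
    def test_bounded_and_monotone(self, ph, pka, slope):
        f = boltzmann_fraction(ph, pka, slope)
        assert 0.0 <= f <= 1.0
        assert boltzmann_fraction(ph + 0.5, pka, slope) >= f


class TestSternVolmer:
    def test_limits_and_hand_value(self):
        assert stern_volmer_intensity(3.0, 0.01, 0.0) == pytest.approx(3.0)
        assert stern_volmer_intensity(1.0, 0.01, 100.0) == pytest.approx(0.5)
        assert stern_volmer_intensity(2.5, 0.0, 1e4) == pytest.approx(2.5)

    @pytest.mark.parametrize("bad", [(-1, 0.01, 10), (1, -0.01, 10), (1, 0.01, -5)])
    def test_negative_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            stern_volmer_intensity(*bad)

    def test_strictly_decreasing(self):
        po2 = np.linspace(0, 400, 50)
        out = stern_volmer_intensity(1.0, 0.02, po2)
        assert np.all(np.diff(out) < 0)


class TestEmitSpectrum:
    def test_nonnegative_everywhere(self, params, grid):
        for ph in (3, 5, 7, 9, 12):
            for po2 in (0, 50, 195, 400):
                assert np.all(emit_spectrum(ph, po2, params, grid) >= 0)

    def test_o2_band_monotone_in_po2_over_grid(self, params, grid):
        """O2-band intensity strictly decreasing in pO2 at every fixed pH."""
        i770 = int(np.argmin(np.abs(grid.values - 770.0)))
        for ph in np.linspace(3, 12, 10):
            vals = [
                emit_spectrum(ph, po2, params, grid)[i770]
                for po2 in np.linspace(0, 390, 10)
            ]
            assert np.all(np.diff(vals) < 0)

    def test_unquenched_limit_at_anoxia(self, params, grid):
        i770 = int(np.argmin(np.abs(grid.values - 770.0)))
        s0 = emit_spectrum(7.0, 0.0, params, grid)[i770]
        for po2 in (1.0, 50.0, 195.0):
            assert emit_spectrum(7.0, po2, params, grid)[i770] < s0

    @pytest.mark.parametrize("po2", [0.0, 100.0, 195.0])
    def test_isosbestic_crossing_near_530(self, params, grid, po2):
        """All pH spectra at fixed pO2 share a crossing within 530 +/- 6 nm."""
        specs = np.stack(
            [emit_spectrum(ph, po2, params, grid) for ph in np.arange(4.0, 11.1, 1.0)]
        )
        lam = grid.values
        window = (lam >= 500) & (lam <= 560)
        spread = specs.max(axis=0) - specs.min(axis=0)
        crossing = lam[window][np.argmin(spread[window])]
        assert abs(crossing - 530.0) <= 6.0

    def test_stern_volmer_halving_propagates(self, params, grid):
        """At K_SV * pO2 = 1 the O2-band peak is exactly half its anoxic value."""
        i770 = int(np.argmin(np.abs(grid.values - 770.0)))
        po2_half = 1.0 / params.K_SV
        s0 = emit_spectrum(7.0, 0.0, params, grid)
        s1 = emit_spectrum(7.0, po2_half, params, grid)
        assert s1[i770] / s0[i770] == pytest.approx(0.5, rel=1e-9)

    def test_no_crosstalk_is_exact_band_sum(self, no_crosstalk_params, grid):
        """With cross-talk off, band-integrated intensities match the
        closed-form Boltzmann / Stern-Volmer factors to 1e-9."""
        p = no_crosstalk_params
        lam = grid.values
        for ph in (4.0, 6.5, 9.0):
            for po2 in (0.0, 80.0, 195.0):
                comps = emit_components(ph, po2, p, grid)
                f = boltzmann_fraction(ph, p.pKa, p.boltzmann_slope)
                expected = {
                    "acid": (1 - f) * p.acid_band.amplitude
                    * p.acid_band.profile(lam).sum(),
                    "base": f * p.base_band.amplitude * p.base_band.profile(lam).sum(),
                    "ref": p.ref_band.amplitude * p.ref_band.profile(lam).sum(),
                    "o2": stern_volmer_intensity(p.o2_band.amplitude, p.K_SV, po2)
                    * p.o2_band.profile(lam).sum(),
                }
                for key, want in expected.items():
                    assert comps[key].sum() == pytest.approx(want, rel=1e-9)
                total = emit_spectrum(ph, po2, p, grid)
                assert np.allclose(total, sum(comps.values()), rtol=1e-12)


class TestCalibrationCube:
    def test_zero_noise_pixels_identical(self, noiseless_params, grid):
        cube, label = generate_calibration_cube(
            6.0, 30.0, noiseless_params, grid, shape=(6, 7), seed=0
        )
        base = emit_spectrum(6.0, 30.0, noiseless_params, grid)
        assert np.allclose(cube.data, base[None, None, :])
        assert label == {"ph": 6.0, "po2": 30.0, "seed": 0}

    def test_seed_reproducibility(self, params, grid):
        c1, _ = generate_calibration_cube(7.0, 50.0, params, grid, (8, 8), seed=3)
        c2, _ = generate_calibration_cube(7.0, 50.0, params, grid, (8, 8), seed=3)
        assert np.array_equal(c1.data, c2.data)

    def test_noise_sd_recovered(self, params, grid):
        """Empirical per-band pixel sd converges to noise_sd (50x50 cube)."""
        cube, _ = generate_calibration_cube(7.0, 50.0, params, grid, (50, 50), seed=1)
        sds = cube.data.reshape(-1, len(grid)).std(axis=0)
        # clipping at zero only bites where the signal is ~0; check a strong band
        i_ref = int(np.argmin(np.abs(grid.values - 535.0)))
        assert sds[i_ref] == pytest.approx(params.noise_sd, rel=0.1)

    def test_frame_smaller_than_tile_rejected(self, params, grid):
        with pytest.raises(ValueError):
            generate_calibration_cube(7.0, 0.0, params, grid, shape=(4, 30))


class TestCalibrationSet:
    def test_single_point_budget(self, params, grid):
        t = generate_calibration_set([7.0], [0.0], 10, params, grid, seed=0)
        assert len(t) == 10
        assert np.all(t.ph == 7.0) and np.all(t.po2 == 0.0)

    def test_imbalanced_preset_overweights_extremes(self, params, grid):
        po2_pts = [0.0, 50.0, 100.0, 150.0, 195.0]
        t = generate_calibration_set(
            [6.0, 7.0], po2_pts, "imbalanced", params, grid, seed=0
        )
        counts = {p: int(np.sum(t.po2 == p)) for p in po2_pts}
        median = np.median(list(counts.values()))
        assert counts[0.0] > median
        assert counts[195.0] > median

    def test_seed_reproducibility(self, params, grid):
        a = generate_calibration_set([5, 7], [0, 100], 5, params, grid, seed=9)
        b = generate_calibration_set([5, 7], [0, 100], 5, params, grid, seed=9)
        assert np.array_equal(a.spectra, b.spectra)

    def test_zero_budget_warns_and_returns_empty(self, params, grid):
        with pytest.warns(UserWarning, match="zero sample budget"):
            t = generate_calibration_set([7.0], [0.0], 0, params, grid, seed=0)
        assert len(t) == 0


class TestGradientScene:
    def test_constant_scene_matches_calibration_cube(self, params, grid):
        spec = SceneSpec(height=6, width=7, ph_field=6.5, po2_field=80.0, seed=4)
        cube, truth = generate_gradient_scene(spec, params, grid)
        ref, _ = generate_calibration_cube(6.5, 80.0, params, grid, (6, 7), seed=4)
        assert np.array_equal(cube.data, ref.data)
        assert np.all(truth.ph_map == 6.5)
        assert np.all(truth.valid_mask)

    def test_ramp_ground_truth_is_the_ramp(self, noiseless_params, grid):
        w = 20
        ramp = np.tile(np.linspace(5.0, 9.0, w), (6, 1))
        spec = SceneSpec(height=6, width=w, ph_field=ramp, po2_field=50.0, seed=0)
        _, truth = generate_gradient_scene(spec, noiseless_params, grid)
        assert np.array_equal(truth.ph_map, ramp)
        assert truth.valid_mask.all()

    def test_mismatched_field_shape_rejected(self, params, grid):
        spec = SceneSpec(
            height=4, width=5, ph_field=np.zeros((3, 5)) + 7, po2_field=0.0
        )
        with pytest.raises(ValueError, match="shape"):
            generate_gradient_scene(spec, params, grid)

    def test_seed_reproducibility(self, params, grid):
        spec = SceneSpec(height=5, width=5, ph_field=7.0, po2_field=10.0, seed=2)
        a, _ = generate_gradient_scene(spec, params, grid)
        b, _ = generate_gradient_scene(spec, params, grid)
        assert np.array_equal(a.data, b.data)


class TestParamValidation:
    def test_crosstalk_bounds(self):
        with pytest.raises(ValueError):
            SpectralModelParams(crosstalk_acid=1.5)
        with pytest.raises(ValueError):
            SpectralModelParams(crosstalk_ref=-0.1)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            Band(500.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            Band(500.0, 10.0, -0.5)

    def test_negative_ksv_rejected(self):
        with pytest.raises(ValueError):
            SpectralModelParams(K_SV=-0.01)
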