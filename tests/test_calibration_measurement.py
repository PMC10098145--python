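"""Calibration, windowing, energy correction, and the linear forward model.

Wave-simulation-backed checks run on the coarse ``tiny_2d`` preset via
session fixtures.
"""

import dataclasses

import numpy as np
import pytest

from paise import (
    CalibrationMatrix,
    FovGrid,
    ImageEstimate,
    PressureTrace,
    TimeWindow,
    WidefieldMeasurement,
    apply_window,
    boundary_safe_window,
    calibrate_direct,
    energy_normalize,
    get_preset,
    place_fov_pixels,
    project_widefield,
    rubber_layer,
    synthesize_widefield,
)


class TestBoundarySafeWindow:
    def test_six_cm_pipe(self):
        params = get_preset("fig3_2d").params
        w = boundary_safe_window(params)
        assert w.t_start == 0.0
        assert w.t_end == pytest.approx(30.51e-6, rel=1e-3)

    def test_thirty_mm_pipe(self):
        params = get_preset("fig4_2d").params
        assert params.pipe_length == 30e-3
        assert boundary_safe_window(params).t_end == pytest.approx(
            15.25e-6, rel=1e-3)

    def test_proportional_to_pipe_length(self):
        p1 = get_preset("demo_2d").params
        p2 = dataclasses.replace(p1, pipe_length=2 * p1.pipe_length)
        assert boundary_safe_window(p2).t_end == pytest.approx(
            2 * boundary_safe_window(p1).t_end)


def _trace(n=100, dt=1e-8):
    return PressureTrace(np.arange(n, dtype=float), dt)


class TestApplyWindow:
    def test_full_span_identity(self):
        tr = _trace()
        out = apply_window(tr, TimeWindow(0.0, 100 * 1e-8))
        assert np.array_equal(out.values, tr.values)

    def test_sample_counting(self):
        out = apply_window(_trace(), TimeWindow(0.0, 10 * 1e-8))
        assert out.nt == 10

    def test_idempotent(self):
        w = TimeWindow(2e-8, 50e-8)
        once = apply_window(_trace(), w)
        twice = apply_window(once, w)
        assert np.array_equal(once.values, twice.values)
        assert once.t0 == twice.t0

    def test_window_beyond_end_rejected(self):
        with pytest.raises(ValueError, match="recorded duration"):
            apply_window(_trace(), TimeWindow(0.0, 1e-5))

    def test_commutes_with_projection(self):
        rng = np.random.default_rng(0)
        K = CalibrationMatrix(rng.standard_normal((100, 5)),
                              FovGrid.synthetic((5,)), dt=1e-8)
        P = ImageEstimate(rng.random(5), K.fov)
        w = TimeWindow(1e-7, 6e-7)
        a = apply_window(project_widefield(K, P), w).values
        b = project_widefield(apply_window(K, w), P).values
        assert np.array_equal(a, b)


class TestEnergyNormalize:
    def test_scaling(self):
        m = WidefieldMeasurement(PressureTrace(np.array([2.0, 4.0]), 1e-8),
                                 pulse_energy=2.0)
        out = energy_normalize(m)
        assert np.allclose(out.trace.values, [1.0, 2.0])
        assert out.pulse_energy == 1.0

    def test_unit_energy_identity(self):
        m = WidefieldMeasurement(PressureTrace(np.array([3.0]), 1e-8))
        assert np.array_equal(energy_normalize(m).trace.values, m.trace.values)

    def test_idempotent(self):
        m = WidefieldMeasurement(PressureTrace(np.arange(4.0), 1e-8),
                                 pulse_energy=5.0)
        once = energy_normalize(m)
        twice = energy_normalize(once)
        assert np.array_equal(once.trace.values, twice.trace.values)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            WidefieldMeasurement(PressureTrace(np.zeros(3), 1e-8),
                                 pulse_energy=0.0)


class TestProjectWidefield:
    def test_basis_vector_returns_column(self):
        rng = np.random.default_rng(1)
        K = CalibrationMatrix(rng.standard_normal((50, 4)),
                              FovGrid.synthetic((4,)), dt=1e-8)
        e2 = np.zeros(4)
        e2[2] = 1.0
        out = project_widefield(K, ImageEstimate(e2, K.fov))
        assert np.array_equal(out.values, K.matrix[:, 2])

    def test_zero_image_zero_trace(self):
        K = CalibrationMatrix(np.ones((10, 3)), FovGrid.synthetic((3,)), dt=1e-8)
        assert not project_widefield(K, ImageEstimate(np.zeros(3), K.fov)).values.any()

    def test_matches_explicit_summation(self):
        rng = np.random.default_rng(2)
        K = CalibrationMatrix(rng.standard_normal((30, 6)),
                              FovGrid.synthetic((6,)), dt=1e-8)
        P = ImageEstimate(rng.random(6), K.fov)
        loop = sum(K.matrix[:, i] * P.values[i] for i in range(6))
        fast = project_widefield(K, P).values
        assert np.abs(fast - loop).max() < 1e-12 * np.abs(loop).max()

    def test_fov_mismatch_rejected(self):
        K = CalibrationMatrix(np.ones((10, 3)), FovGrid.synthetic((3,)), dt=1e-8)
        P = ImageEstimate(np.zeros(4), FovGrid.synthetic((4,)))
        with pytest.raises(ValueError):
            project_widefield(K, P)


class TestSimulatedCalibration:
    """Wave-backed checks on the coarse preset (session-cached)."""

    def test_single_pixel_matrix_matches_direct_simulation(self, tiny):
        pre = tiny.preset
        fov1 = place_fov_pixels(pre.params, 0.0, pre.fov_pitch,
                                pre.sim.dx, pre.sim.pml_cells)
        K1 = calibrate_direct(tiny.grid, pre.params, fov1, tiny.cal_variant,
                              pre.source_width, pre.sim.cutoff_wavelength)
        assert K1.n_pixels == 1
        assert np.abs(K1.matrix[:, 0]).max() > 0

    def test_columns_all_nonzero(self, tiny):
        assert (np.abs(tiny.K.matrix).max(axis=0) > 0).all()

    def test_indicator_phantom_reproduces_column(self, tiny):
        """A single-pixel phantom measured under the calibration variant
        equals pulse_energy times the calibration column (linearity)."""
        j = 1
        vals = np.zeros(tiny.fov.shape)
        vals[j] = 1.0
        m = synthesize_widefield(
            tiny.grid, tiny.preset.params, tiny.cal_variant,
            ImageEstimate(vals, tiny.fov), tiny.fov, pulse_energy=2.0,
            source_width=tiny.preset.source_width,
            cutoff_wavelength=tiny.preset.sim.cutoff_wavelength)
        w = tiny.window
        a = apply_window(m, w).trace.values
        b = 2.0 * apply_window(tiny.K, w).matrix[:, j]
        assert np.linalg.norm(a - b) < 1e-3 * np.linalg.norm(b)

    def test_model_fidelity_within_window(self, tiny):
        """Full-physics widefield trace matches K P inside the safe window."""
        ph = tiny.phantom("c_shape")
        m = tiny.measure("c_shape", "matched")
        w = tiny.window
        s_w = apply_window(m, w).trace.values
        proj = project_widefield(apply_window(tiny.K, w), ph.values).values
        assert np.linalg.norm(s_w - proj) < 0.05 * np.linalg.norm(s_w)

    def test_zero_phantom_zero_trace(self, tiny):
        m = synthesize_widefield(
            tiny.grid, tiny.preset.params, tiny.cal_variant,
            ImageEstimate(np.zeros(tiny.fov.shape), tiny.fov), tiny.fov,
            source_width=tiny.preset.source_width,
            cutoff_wavelength=tiny.preset.sim.cutoff_wavelength)
        assert np.abs(m.trace.values).max() == 0.0

    def test_noise_seeded_determinism(self, tiny):
        ph = tiny.phantom("c_shape")
        kw = dict(source_width=tiny.preset.source_width,
                  cutoff_wavelength=tiny.preset.sim.cutoff_wavelength,
                  noise_snr_db=30.0, seed=42)
        m1 = synthesize_widefield(tiny.grid, tiny.preset.params,
                                  tiny.cal_variant, ph.values, tiny.fov, **kw)
        m2 = synthesize_widefield(tiny.grid, tiny.preset.params,
                                  tiny.cal_variant, ph.values, tiny.fov, **kw)
        assert np.array_equal(m1.trace.values, m2.trace.values)

    def test_negative_phantom_rejected(self, tiny):
        vals = np.zeros(tiny.fov.shape)
        vals[0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            synthesize_widefield(tiny.grid, tiny.preset.params,
                                 tiny.cal_variant,
                                 ImageEstimate(vals, tiny.fov), tiny.fov)

    def test_energy_normalization_removes_pulse_energy(self, tiny):
        ph = tiny.phantom("c_shape")
        kw = dict(source_width=tiny.preset.source_width,
                  cutoff_wavelength=tiny.preset.sim.cutoff_wavelength)
        m1 = synthesize_widefield(tiny.grid, tiny.preset.params,
                                  tiny.cal_variant, ph.values, tiny.fov,
                                  pulse_energy=3.0, **kw)
        m2 = synthesize_widefield(tiny.grid, tiny.preset.params,
                                  tiny.cal_variant, ph.values, tiny.fov,
                                  pulse_energy=1.0, **kw)
        assert np.allclose(energy_normalize(m1).trace.values,
                           m2.trace.values, rtol=0, atol=1e-12)

    def test_reciprocal_matches_direct(self, tiny):
        """One-run reciprocity calibration agrees with pointwise scanning."""
        w = tiny.window
        Kd = apply_window(tiny.K, w)
        Kr = apply_window(tiny.K_reciprocal, w)
        for i in range(tiny.fov.n_pixels):
            r = np.corrcoef(Kd.matrix[:, i], Kr.matrix[:, i])[0, 1]
            assert r > 0.95

    def test_mismatched_fov_rejected(self, tiny):
        pre = tiny.preset
        other = place_fov_pixels(pre.params, 0.0, pre.fov_pitch,
                                 pre.sim.dx, pre.sim.pml_cells)
        P = ImageEstimate(np.zeros(other.shape), other)
        with pytest.raises(ValueError):
            project_widefield(tiny.K, P)
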