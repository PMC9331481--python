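"""Phasor transform, calibration, and universal-circle geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import retflim as rf
from retflim.errors import CalibrationError, InvalidInputError
from conftest import calibrated_mono_field


def _cube_from_counts(counts, period=12.5, t0=0.0):
    counts = np.asarray(counts, float)
    n = counts.shape[-1]
    dt = period / n
    return rf.DecayCube(
        counts=counts.reshape(1, 1, n),
        channel="test",
        time_axis_ns=t0 + np.arange(n) * dt,
    )


class TestTransform:
    def test_instantaneous_pulse_at_unit_point(self):
        counts = np.zeros(64)
        counts[0] = 1000  # all photons at t = 0
        f = rf.phasor_transform(_cube_from_counts(counts))
        assert f.g[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_counts_at_origin(self):
        f = rf.phasor_transform(_cube_from_counts(np.full(64, 10.0)))
        assert abs(f.g[0, 0]) < 1e-12
        assert abs(f.s[0, 0]) < 1e-12

    def test_empty_cube_rejected(self):
        with pytest.raises(InvalidInputError):
            rf.phasor_transform(_cube_from_counts(np.zeros(32)))

    def test_zero_intensity_pixels_flagged_invalid(self, instrument):
        cube = rf.simulate_reference_cube(instrument, 1.0, 100, shape=(2, 2),
                                          poisson=False)
        cube.counts[0, 0, :] = 0
        f = rf.phasor_transform(cube)
        assert not f.valid[0, 0]
        assert f.valid[1, 1]

    def test_known_lifetime_position_after_calibration(self, instrument):
        """tau = 0.4 ns at an 80 MHz period sits at (0.9611, 0.1932)."""
        f = calibrated_mono_field(instrument, 0.4)
        assert f.g[0, 0] == pytest.approx(0.96114, abs=5e-4)
        assert f.s[0, 0] == pytest.approx(0.19325, abs=5e-4)


class TestCalibration:
    def test_self_calibration_lands_on_closed_form(self, instrument):
        cube = rf.simulate_reference_cube(instrument, 1.5, 1e5, shape=(8, 8),
                                          poisson=True, seed=4)
        f = rf.calibrate(rf.phasor_transform(cube), cube, 1.5)
        p = rf.lifetime_to_phasor(1.5, instrument.omega())
        com = rf.phasor_center_of_mass(f)
        assert com.distance(p) < 0.005

    def test_identity_irf_calibration_is_near_identity(self):
        inst = rf.InstrumentModel(n_bins=4096, irf_fwhm_ns=0.0, irf_center_ns=0.0)
        cube = rf.simulate_reference_cube(inst, 1.0, 1e6, shape=(2, 2),
                                          poisson=False)
        raw = rf.phasor_transform(cube)
        cal = rf.calibrate(raw, cube, 1.0)
        assert np.max(np.abs(cal.g - raw.g)) < 1e-3
        assert np.max(np.abs(cal.s - raw.s)) < 1e-3

    def test_shg_reference_maps_to_unit_point(self, instrument):
        cube = rf.simulate_reference_cube(instrument, 0.0, 1e6, poisson=False)
        f = rf.calibrate(rf.phasor_transform(cube), cube, 0.0)
        com = rf.phasor_center_of_mass(f)
        assert com.distance(rf.PhasorPoint(1.0, 0.0)) < 1e-9

    def test_zero_intensity_reference_rejected(self, instrument):
        cube = rf.simulate_reference_cube(instrument, 1.0, 100, poisson=False)
        empty = rf.DecayCube(
            counts=np.zeros_like(cube.counts),
            channel=cube.channel,
            time_axis_ns=cube.time_axis_ns,
        )
        f = rf.phasor_transform(cube)
        with pytest.raises((CalibrationError, InvalidInputError)):
            rf.calibrate(f, empty, 1.0)


class TestLifetimeGeometry:
    def test_zero_lifetime_at_unit_point(self):
        p = rf.lifetime_to_phasor(0.0, 0.5)
        assert (p.g, p.s) == (1.0, 0.0)

    def test_omega_tau_one_at_circle_top(self):
        p = rf.lifetime_to_phasor(2.0, 0.5)
        assert p.g == pytest.approx(0.5)
        assert p.s == pytest.approx(0.5)

    def test_free_fad_lifetime_on_circle(self):
        omega = 2 * np.pi / 12.5
        p = rf.lifetime_to_phasor(2.6, omega)
        assert (p.g - 0.5) ** 2 + p.s**2 == pytest.approx(0.25, abs=1e-12)
        assert p.s > 0

    def test_negative_tau_rejected(self):
        with pytest.raises(InvalidInputError):
            rf.lifetime_to_phasor(-1.0, 0.5)

    @given(st.floats(0.01, 20.0), st.integers(1, 4))
    def test_universal_circle_and_harmonic_ratio(self, tau, harmonic):
        omega = 2 * np.pi * harmonic / 12.5
        p = rf.lifetime_to_phasor(tau, omega)
        assert (p.g - 0.5) ** 2 + p.s**2 == pytest.approx(0.25, abs=1e-12)
        assert p.s / p.g == pytest.approx(omega * tau, rel=1e-9)

    def test_increasing_tau_moves_toward_origin(self):
        omega = 2 * np.pi / 12.5
        taus = [0.1, 0.4, 1.0, 2.6, 6.0, 20.0]
        gs = [rf.lifetime_to_phasor(t, omega).g for t in taus]
        assert gs == sorted(gs, reverse=True)


class TestSimulatedPhasorProperties:
    @pytest.mark.parametrize("tau,harmonic", [(0.4, 1), (2.6, 1), (1.0, 2), (3.2, 3)])
    def test_calibrated_mono_exponential_on_circle(self, fine_instrument, tau, harmonic):
        f = calibrated_mono_field(fine_instrument, tau, harmonic=harmonic)
        r2 = (f.g[0, 0] - 0.5) ** 2 + f.s[0, 0] ** 2
        assert abs(np.sqrt(r2) - 0.5) < 1e-6

    def test_mixture_linearity(self, instrument):
        """The phasor of a two-component decay is the fractional-intensity
        combination of the component phasors (closed-form oracle)."""
        omega = instrument.omega()
        ref = rf.simulate_reference_cube(instrument, 1.0, 1e6, poisson=False)
        for frac in (0.25, 0.589, 0.8):
            curve = (1 - frac) * rf.component_curve(0.4, instrument) \
                + frac * rf.component_curve(3.2, instrument)
            cube = rf.DecayCube(
                counts=np.broadcast_to(1e6 * curve, (1, 1, instrument.n_bins)).copy(),
                channel="nadph",
                time_axis_ns=instrument.time_axis_ns,
            )
            f = rf.calibrate(rf.phasor_transform(cube), ref, 1.0)
            pf = rf.lifetime_to_phasor(0.4, omega)
            pb = rf.lifetime_to_phasor(3.2, omega)
            g_exp = (1 - frac) * pf.g + frac * pb.g
            s_exp = (1 - frac) * pf.s + frac * pb.s
            assert f.g[0, 0] == pytest.approx(g_exp, abs=5e-4)
            assert f.s[0, 0] == pytest.approx(s_exp, abs=5e-4)


class TestCenterOfMass:
    def _field(self, gs, ss, inten):
        return rf.PhasorField(
            g=np.asarray(gs, float)[None, :],
            s=np.asarray(ss, float)[None, :],
            intensity=np.asarray(inten, float)[None, :],
            harmonic=1,
            angular_frequency=0.5,
        )

    def test_single_pixel(self):
        f = self._field([0.3], [0.2], [10])
        com = rf.phasor_center_of_mass(f)
        assert (com.g, com.s) == (0.3, 0.2)

    def test_equal_weights_midpoint(self):
        f = self._field([0.0, 1.0], [0.0, 0.0], [5, 5])
        assert rf.phasor_center_of_mass(f).g == pytest.approx(0.5)

    def test_photon_weighted(self):
        f = self._field([0.0, 1.0], [0.0, 0.0], [1, 3])
        assert rf.phasor_center_of_mass(f).g == pytest.approx(0.75)

    def test_unweighted_option(self):
        f = self._field([0.0, 1.0], [0.0, 0.0], [1, 3])
        assert rf.phasor_center_of_mass(f, weighted=False).g == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        f = self._field([0.1], [0.1], [1])
        with pytest.raises(InvalidInputError):
            rf.phasor_center_of_mass(f, np.zeros((1, 1), bool))


class TestMedianFilter:
    def _flat_field(self, n=5, g=0.4, s=0.3):
        return rf.PhasorField(
            g=np.full((n, n), g),
            s=np.full((n, n), s),
            intensity=np.ones((n, n)),
            harmonic=1,
            angular_frequency=0.5,
        )

    def test_constant_field_unchanged(self):
        f = self._flat_field()
        out = rf.median_filter_phasor(f, 3)
        np.testing.assert_allclose(out.g, f.g)

    def test_window_one_is_identity(self):
        f = self._flat_field()
        out = rf.median_filter_phasor(f, 1)
        np.testing.assert_array_equal(out.g, f.g)

    def test_salt_outlier_removed(self):
        f = self._flat_field()
        f.g[2, 2] = 0.99
        out = rf.median_filter_phasor(f, 3)
        assert out.g[2, 2] == pytest.approx(0.4)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidInputError):
            rf.median_filter_phasor(self._flat_field(), 4)
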