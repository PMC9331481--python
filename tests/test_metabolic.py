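"""Metabolic trajectory geometry and bound-fraction estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import retflim as rf
from retflim.errors import DegenerateTrajectoryError, InvalidInputError
from retflim.zoning import ROI
from conftest import calibrated_mono_field

OMEGA = 2 * np.pi / 12.5


class TestFitTrajectory:
    def test_diameter_chord(self):
        """A COM at the circle center with the free anchor at (1, 0)
        extrapolates to the antipodal point (0, 0)."""
        traj = rf.fit_trajectory(rf.PhasorPoint(0.5, 0.0), 0.0, OMEGA)
        assert traj.free_anchor.g == pytest.approx(1.0)
        assert traj.bound_anchor.g == pytest.approx(0.0, abs=1e-12)
        assert traj.bound_anchor.s == pytest.approx(0.0, abs=1e-12)

    def test_com_on_circle_is_its_own_anchor(self):
        com = rf.lifetime_to_phasor(3.2, OMEGA)
        traj = rf.fit_trajectory(com, 0.4, OMEGA)
        assert traj.bound_anchor.distance(com) < 1e-9

    def test_bound_anchor_matches_quadratic_roots_oracle(self):
        """Line-circle intersection solved independently with np.roots."""
        com = rf.PhasorPoint(0.7, 0.3)
        traj = rf.fit_trajectory(com, 0.4, OMEGA)
        f = np.array([traj.free_anchor.g, traj.free_anchor.s])
        d = np.array([com.g, com.s]) - f
        # |f + u d - c|^2 = 1/4 as a polynomial in u
        c = np.array([0.5, 0.0])
        poly = [d @ d, 2 * d @ (f - c), (f - c) @ (f - c) - 0.25]
        roots = np.roots(poly)
        other = roots[np.argmax(np.abs(roots))]
        expected = f + other.real * d
        assert traj.bound_anchor.g == pytest.approx(expected[0], abs=1e-12)
        assert traj.bound_anchor.s == pytest.approx(expected[1], abs=1e-12)

    def test_anchors_satisfy_circle_equation(self):
        for g, s in [(0.6, 0.2), (0.5, 0.25), (0.8, 0.1)]:
            traj = rf.fit_trajectory(rf.PhasorPoint(g, s), 0.4, OMEGA)
            for p in (traj.free_anchor, traj.bound_anchor):
                assert (p.g - 0.5) ** 2 + p.s**2 == pytest.approx(0.25, abs=1e-9)

    def test_com_at_anchor_rejected(self):
        anchor = rf.lifetime_to_phasor(0.4, OMEGA)
        with pytest.raises(DegenerateTrajectoryError):
            rf.fit_trajectory(anchor, 0.4, OMEGA)

    def test_com_slightly_outside_clamped_with_warning(self):
        p = rf.lifetime_to_phasor(1.0, OMEGA)
        outside = rf.PhasorPoint(p.g * 1.0 + 0.01, p.s + 0.01)
        with pytest.warns(UserWarning, match="clamped"):
            traj = rf.fit_trajectory(outside, 0.4, OMEGA)
        b = traj.bound_anchor
        assert (b.g - 0.5) ** 2 + b.s**2 == pytest.approx(0.25, abs=1e-9)

    def test_com_far_outside_rejected(self):
        with pytest.raises(InvalidInputError):
            rf.fit_trajectory(rf.PhasorPoint(1.4, 0.4), 0.4, OMEGA)


class TestBoundFraction:
    @pytest.fixture()
    def traj(self):
        return rf.fit_trajectory(rf.PhasorPoint(0.6, 0.35), 0.4, OMEGA)

    def test_free_anchor_is_zero(self, traj):
        assert rf.bound_fraction(traj, traj.free_anchor) == 0.0

    def test_bound_anchor_is_hundred(self, traj):
        assert rf.bound_fraction(traj, traj.bound_anchor) == 100.0

    def test_chord_midpoint_is_fifty(self, traj):
        mid = rf.PhasorPoint(
            0.5 * (traj.free_anchor.g + traj.bound_anchor.g),
            0.5 * (traj.free_anchor.s + traj.bound_anchor.s),
        )
        assert rf.bound_fraction(traj, mid) == pytest.approx(50.0, abs=1e-9)

    @given(st.floats(0.0, 1.0))
    def test_linearity_in_mixture_fraction(self, frac):
        traj = rf.fit_trajectory(rf.PhasorPoint(0.6, 0.35), 0.4, OMEGA)
        fa, ba = traj.free_anchor, traj.bound_anchor
        com = rf.PhasorPoint(
            (1 - frac) * fa.g + frac * ba.g, (1 - frac) * fa.s + frac * ba.s
        )
        assert rf.bound_fraction(traj, com) == pytest.approx(100 * frac, abs=1e-6)

    def test_fad_free_fraction_convention(self):
        """The FAD trajectory is anchored at the free-FAD lifetime and
        reported from the free end: 100 % free at the anchor."""
        com = rf.PhasorPoint(0.55, 0.3)
        traj = rf.fit_trajectory(com, 2.6, OMEGA)
        assert rf.fad_free_fraction(traj, traj.free_anchor) == 100.0
        assert rf.fad_free_fraction(traj, traj.bound_anchor) == 0.0

    def test_simulated_roi_recovers_ground_truth(self, instrument):
        """A uniform 58.9 %-bound NAD(P)H region is recovered within 1 pp."""
        ph = rf.make_phantom(200, 300, 1.0, seed=8, vessels=False)
        grid = rf.layer_metabolic_profile(ph, 58.9, 58.9)
        cube = rf.simulate_decay_cube(
            ph, instrument, "nadph", 1e4, ground_truth_pct=grid, seed=8
        )
        ref = rf.simulate_reference_cube(instrument, 1.0, poisson=False)
        field = rf.calibrate(rf.phasor_transform(cube), ref, 1.0)
        com = rf.phasor_center_of_mass(field, ph.mask("onl"))
        traj = rf.fit_trajectory(com, 0.4, field.angular_frequency)
        assert rf.bound_fraction(traj, com) == pytest.approx(58.9, abs=1.0)


class TestAnalyzeRois:
    def _field_and_rois(self, instrument, bound_pct=(58.9, 60.9)):
        ph = rf.make_phantom(1600, 300, 2.0, seed=10, vessels=False)
        grid = rf.layer_metabolic_profile(ph, *bound_pct)
        cube = rf.simulate_decay_cube(
            ph, instrument, "nadph", 1e4, ground_truth_pct=grid, seed=10
        )
        ref = rf.simulate_reference_cube(instrument, 1.0, poisson=False)
        field = rf.calibrate(rf.phasor_transform(cube), ref, 1.0)
        zones = rf.build_zones(ph)
        rois = rf.make_rois(zones)
        return ph, field, rois

    def test_uncalibrated_field_rejected(self, instrument):
        ph, field, rois = self._field_and_rois(instrument)
        raw = rf.PhasorField(
            g=field.g, s=field.s, intensity=field.intensity,
            harmonic=1, angular_frequency=field.angular_frequency,
            calibrated=False,
        )
        with pytest.raises(InvalidInputError):
            rf.analyze_rois(raw, rois, 0.4)

    def test_region_ordering_preserved(self, instrument):
        """Ground truths 58.9 (outer) / 60.9 (inner) keep inner > outer."""
        ph, field, rois = self._field_and_rois(instrument)
        results = rf.analyze_rois(field, rois, 0.4)
        outer = np.mean([r.bound_pct for r in results if r.region == "outer"])
        inner = np.mean([r.bound_pct for r in results if r.region == "inner"])
        assert inner > outer

    def test_pure_free_roi_is_zero_bound(self, instrument):
        ph = rf.make_phantom(100, 300, 1.0, seed=1, vessels=False)
        grid = rf.layer_metabolic_profile(ph, 0.0, 0.0)
        cube = rf.simulate_decay_cube(
            ph, instrument, "nadph", 1e5, ground_truth_pct=grid, poisson=False
        )
        ref = rf.simulate_reference_cube(instrument, 1.0, poisson=False)
        field = rf.calibrate(rf.phasor_transform(cube), ref, 1.0)
        roi = ROI("onl", ph.mask("onl"), "central", "outer", "superior", 100.0)
        res = rf.analyze_rois(field, [roi], 0.4)
        assert res[0].bound_pct == pytest.approx(0.0, abs=0.2)

    def test_exclusion_mask_restricts_com(self, instrument):
        """With half an ROI excluded, the COM is that of the kept half."""
        ph, field, rois = self._field_and_rois(instrument)
        roi = rois.rois[0]
        cols = np.flatnonzero(roi.mask.any(axis=0))
        excl = np.zeros(ph.shape, dtype=bool)
        excl[:, cols[: cols.size // 2]] = True
        res = rf.analyze_rois(field, [roi], 0.4, exclusion_mask=excl)[0]
        manual_mask = roi.mask & ~excl & field.valid
        manual = rf.phasor_center_of_mass(field, manual_mask)
        assert res.com.distance(manual) < 1e-12
        assert res.n_pixels == int(manual_mask.sum())

    def test_fully_excluded_rois_error(self, instrument):
        ph, field, rois = self._field_and_rois(instrument)
        excl = np.ones(ph.shape, dtype=bool)
        with pytest.raises(rf.EmptyResultError):
            rf.analyze_rois(field, rois, 0.4, exclusion_mask=excl)

    def test_global_trajectory_mode(self, instrument):
        ph, field, rois = self._field_and_rois(instrument)
        results = rf.analyze_rois(field, rois, 0.4, per_roi_trajectory=False)
        trajs = {id(r.trajectory) for r in results}
        assert len(trajs) == 1


class TestBoundFractionMap:
    def test_map_matches_scalar_path(self, instrument):
        f = calibrated_mono_field(instrument, 1.0, shape=(3, 3))
        com = rf.phasor_center_of_mass(f)
        traj = rf.fit_trajectory(com, 0.4, f.angular_frequency)
        bmap = rf.bound_fraction_map(f, traj)
        expected = rf.bound_fraction(traj, rf.PhasorPoint(f.g[1, 1], f.s[1, 1]))
        assert bmap[1, 1] == pytest.approx(expected, abs=1e-9)
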