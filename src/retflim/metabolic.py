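"""Metabolic trajectory construction and bound-fraction estimation.

The metabolic trajectory is a chord of the universal circle: it starts at
the free-lifetime anchor (0.4 ns for NAD(P)H, 2.6 ns for FAD), passes
through an ROI's phasor center of mass, and is extrapolated to its second
intersection with the circle, which represents the 100 %-bound species.
The bound percentage is the ROI center of mass's relative position along
that chord (orthogonal projection), times 100. Because phasors mix
linearly by fractional intensity, this is a fraction of fluorescence
intensity, not of molecular concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTrajectoryError, EmptyResultError, InvalidInputError
from .phasor import PhasorField, PhasorPoint, lifetime_to_phasor, phasor_center_of_mass

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryModel",
    "BoundFractionResult",
    "fit_trajectory",
    "bound_fraction",
    "fad_free_fraction",
    "analyze_rois",
    "bound_fraction_map",
]

_CENTER = np.array([0.5, 0.0])
_RADIUS = 0.5


@dataclass(frozen=True)
class TrajectoryModel:
    """Chord geometry of one metabolic trajectory.

    ``free_anchor`` is the known free-species lifetime on the circle;
    ``bound_anchor`` is the extrapolated 100 %-bound intersection.
    """

    free_anchor: PhasorPoint
    bound_anchor: PhasorPoint
    free_tau_ns: float
    omega: float

    @property
    def chord_length(self) -> float:
        return self.free_anchor.distance(self.bound_anchor)

    @property
    def bound_tau_ns(self) -> float:
        """Apparent lifetime of the bound anchor, from its circle position."""
        b = self.bound_anchor
        if b.g <= 0:
            return float("inf")
        return b.s / (b.g * self.omega)


@dataclass(frozen=True)
class BoundFractionResult:
    """Per-ROI bound-percentage estimate."""

    roi_id: str
    bound_pct: float
    com: PhasorPoint
    trajectory: TrajectoryModel
    n_pixels: int
    total_photons: float
    zone: str = ""
    region: str = ""
    side: str = ""


def _clamp_to_circle(com: PhasorPoint, tolerance: float) -> PhasorPoint:
    """Radially clamp a point that noise pushed outside the circle."""
    v = np.array([com.g, com.s]) - _CENTER
    r = float(np.linalg.norm(v))
    if r <= _RADIUS:
        return com
    if r > _RADIUS + tolerance:
        raise InvalidInputError(
            f"center of mass lies {r - _RADIUS:.4f} outside the universal "
            f"circle, beyond tolerance {tolerance}"
        )
    warnings.warn(
        "phasor center of mass outside the universal circle; clamped radially",
        stacklevel=3,
    )
    v *= _RADIUS / r
    return PhasorPoint(*(_CENTER + v))


def fit_trajectory(
    com: PhasorPoint,
    free_tau_ns: float,
    omega: float,
    outside_tolerance: float = 0.02,
    anchor_tolerance: float = 1e-3,
) -> TrajectoryModel:
    """Draw the metabolic trajectory through a phasor center of mass.

    The free anchor is placed at ``free_tau_ns`` on the universal circle;
    the line through the anchor and ``com`` is extrapolated to its other
    circle intersection (the quadratic root distinct from the anchor),
    which becomes the bound anchor. A center of mass slightly outside the
    circle (photon noise) is clamped radially within ``outside_tolerance``.
    """
    free = lifetime_to_phasor(free_tau_ns, omega)
    com = _clamp_to_circle(com, outside_tolerance)
    f = np.array([free.g, free.s])
    c = np.array([com.g, com.s])
    d = c - f
    nd = float(np.linalg.norm(d))
    if nd < 1e-12:
        raise DegenerateTrajectoryError(
            "center of mass coincides with the free anchor"
        )
    if nd < anchor_tolerance:
        # An essentially pure-free population: the chord direction is pure
        # noise, and a COM clamped onto the circle next to the anchor would
        # collapse the chord entirely. Use the diameter through the free
        # anchor; the projected fraction stays ~|com - anchor| / 1, i.e. ~0.
        warnings.warn(
            "center of mass within tolerance of the free anchor; "
            "using the diameter as trajectory",
            stacklevel=2,
        )
        bound = f + 2.0 * (_CENTER - f)
        return TrajectoryModel(
            free_anchor=free,
            bound_anchor=PhasorPoint(float(bound[0]), float(bound[1])),
            free_tau_ns=free_tau_ns,
            omega=omega,
        )
    # Points on the line: p(u) = f + u*d. On the circle |p - center|^2 = R^2;
    # u = 0 is a root because the anchor sits on the circle, so the other
    # root is u* = -B/A with A = |d|^2, B = 2 d.(f - center).
    a = float(d @ d)
    b = 2.0 * float(d @ (f - _CENTER))
    u_other = -b / a
    bound = f + u_other * d
    if u_other <= 0:
        # COM lies on the far side of the anchor: the chord through it runs
        # away from the circle interior. Still well-defined geometry, but
        # bound fractions would be negative; flag it.
        raise DegenerateTrajectoryError(
            "extrapolated bound anchor falls behind the free anchor"
        )
    return TrajectoryModel(
        free_anchor=free,
        bound_anchor=PhasorPoint(float(bound[0]), float(bound[1])),
        free_tau_ns=free_tau_ns,
        omega=omega,
    )


def _chord_fraction(traj: TrajectoryModel, com: PhasorPoint) -> float:
    f = np.array([traj.free_anchor.g, traj.free_anchor.s])
    bnd = np.array([traj.bound_anchor.g, traj.bound_anchor.s])
    chord = bnd - f
    L2 = float(chord @ chord)
    if L2 <= 0:
        raise DegenerateTrajectoryError("zero-length trajectory chord")
    u = float((np.array([com.g, com.s]) - f) @ chord) / L2
    return min(max(u, 0.0), 1.0)


def bound_fraction(traj: TrajectoryModel, com: PhasorPoint) -> float:
    """Bound percentage: projection of ``com`` onto the trajectory chord.

    0 at the free anchor, 100 at the bound anchor, clamped to [0, 100].
    """
    return 100.0 * _chord_fraction(traj, com)


def fad_free_fraction(traj: TrajectoryModel, com: PhasorPoint) -> float:
    """Free-FAD percentage: same chord geometry anchored at the free-FAD
    lifetime, reported from the free end (100 at the free anchor)."""
    return 100.0 - bound_fraction(traj, com)


def analyze_rois(
    fieldp: PhasorField,
    rois,
    free_tau_ns: float,
    exclusion_mask: np.ndarray | None = None,
    per_roi_trajectory: bool = True,
    global_com_mask: np.ndarray | None = None,
    weighted: bool = True,
) -> list[BoundFractionResult]:
    """Estimate the bound percentage for every ROI of an ROI set.

    By default each ROI gets its own trajectory through its own center of
    mass (the slider is moved over each ROI). ``per_roi_trajectory=False``
    fits one global trajectory through the center of mass of
    ``global_com_mask`` (or all valid pixels) for cross-ROI comparability.
    ROIs emptied by the exclusion mask are dropped and logged.
    """
    if not fieldp.calibrated:
        raise InvalidInputError("phasor field must be calibrated first")
    roi_list = list(rois)
    if not roi_list:
        raise EmptyResultError("ROI set is empty")

    global_traj = None
    if not per_roi_trajectory:
        com_all = phasor_center_of_mass(fieldp, global_com_mask, weighted=weighted)
        global_traj = fit_trajectory(com_all, free_tau_ns, fieldp.angular_frequency)

    results: list[BoundFractionResult] = []
    for roi in roi_list:
        mask = np.asarray(roi.mask, dtype=bool)
        if exclusion_mask is not None:
            mask = mask & ~np.asarray(exclusion_mask, dtype=bool)
        mask &= fieldp.valid
        if not mask.any():
            logger.info("ROI %s fully excluded; dropped", roi.roi_id)
            continue
        com = phasor_center_of_mass(fieldp, mask, weighted=weighted)
        traj = global_traj or fit_trajectory(
            com, free_tau_ns, fieldp.angular_frequency
        )
        results.append(
            BoundFractionResult(
                roi_id=roi.roi_id,
                bound_pct=bound_fraction(traj, com),
                com=com,
                trajectory=traj,
                n_pixels=int(mask.sum()),
                total_photons=float(fieldp.intensity[mask].sum()),
                zone=getattr(roi, "zone", ""),
                region=getattr(roi, "region", ""),
                side=getattr(roi, "side", ""),
            )
        )
    if not results:
        raise EmptyResultError("every ROI was excluded")
    return results


def bound_fraction_map(
    fieldp: PhasorField, traj: TrajectoryModel, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-pixel bound percentage along one (global) trajectory.

    Used for rainbow-map rendering; NaN outside ``mask``/valid pixels.
    """
    f = np.array([traj.free_anchor.g, traj.free_anchor.s])
    bnd = np.array([traj.bound_anchor.g, traj.bound_anchor.s])
    chord = bnd - f
    L2 = float(chord @ chord)
    if L2 <= 0:
        raise DegenerateTrajectoryError("zero-length trajectory chord")
    u = ((fieldp.g - f[0]) * chord[0] + (fieldp.s - f[1]) * chord[1]) / L2
    out = np.clip(u, 0.0, 1.0) * 100.0
    sel = fieldp.valid if mask is None else (fieldp.valid & np.asarray(mask, bool))
    return np.where(sel, out, np.nan)
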