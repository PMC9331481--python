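"""Phasor-position-based structural segmentation.

Melanin, hemoglobin, and second-harmonic collagen each occupy a distinct
position on the phasor plot, so pixels can be classified by proximity to a
reference phasor — the software analogue of highlighting all pixels whose
lifetime signature matches an ROI picked on the phasor plot. Hemoglobin
and melanin share the 600-650 nm emission band and are separated purely by
phasor position; the second-harmonic signal is effectively instantaneous
and sits at the zero-lifetime point (1, 0), far from any autofluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .phasor import PhasorField, PhasorPoint, phasor_center_of_mass

__all__ = ["PhasorSelector", "phasor_select", "shg_mask", "learn_selector"]


@dataclass(frozen=True)
class PhasorSelector:
    """Circular phasor-plot gate: reference position + selection radius."""

    reference: PhasorPoint
    radius: float
    channel: str = ""
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise InvalidInputError("selection radius must be >= 0")


def phasor_select(
    fieldp: PhasorField,
    selector: PhasorSelector,
    intensity_floor: float = 5.0,
) -> np.ndarray:
    """Boolean mask of pixels whose phasor lies within the selector gate.

    Distance is Euclidean in (g, s); pixels below ``intensity_floor``
    photons are suppressed as background. An empty mask is a valid result.
    """
    if not fieldp.calibrated:
        raise InvalidInputError("phasor field must be calibrated first")
    d2 = (fieldp.g - selector.reference.g) ** 2 + (
        fieldp.s - selector.reference.s
    ) ** 2
    return (
        (d2 <= selector.radius**2)
        & fieldp.valid
        & (fieldp.intensity >= intensity_floor)
    )


def shg_mask(
    fieldp: PhasorField, radius: float = 0.05, intensity_floor: float = 5.0
) -> np.ndarray:
    """Select second-harmonic pixels: phasors at the zero-lifetime point.

    Separates coherent second harmonic from collagen autofluorescence,
    which decays with a finite lifetime and therefore sits well inside the
    circle."""
    sel = PhasorSelector(PhasorPoint(1.0, 0.0), radius, name="shg")
    return phasor_select(fieldp, sel, intensity_floor=intensity_floor)


def learn_selector(
    fieldp: PhasorField,
    seed_mask: np.ndarray,
    name: str = "custom",
    radius_quantile: float = 0.95,
    weighted: bool = True,
) -> PhasorSelector:
    """Learn a selector from a user-drawn seed ROI (e.g. one blood vessel).

    The reference is the seed ROI's phasor center of mass; the radius is
    the given quantile of seed-pixel distances from it, so the gate
    recaptures the seed population and everything sharing its signature.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not (seed_mask & fieldp.valid).any():
        raise InvalidInputError("seed ROI selects no valid pixels")
    ref = phasor_center_of_mass(fieldp, seed_mask, weighted=weighted)
    sel = seed_mask & fieldp.valid
    dist = np.hypot(fieldp.g[sel] - ref.g, fieldp.s[sel] - ref.s)
    radius = float(np.quantile(dist, radius_quantile))
    if radius == 0.0:
        warnings.warn(
            f"selector {name!r}: seed phasors are identical; radius is 0"
        )
    return PhasorSelector(
        reference=ref,
        radius=radius,
        channel=str(fieldp.meta.get("channel", "")),
        name=name,
    )
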