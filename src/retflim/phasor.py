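"""First-harmonic phasor transform and universal-circle geometry.

The phasor of a decay I(t) at harmonic n is the normalized Fourier pair

    g = sum_t I(t) cos(n*omega*t) / sum_t I(t)
    s = sum_t I(t) sin(n*omega*t) / sum_t I(t),

with omega = 2*pi/T the laser repetition angular frequency and t the bin
centers. A mono-exponential lifetime tau sits on the universal circle
(center (1/2, 0), radius 1/2) at g = 1/(1+(omega*tau)^2),
s = omega*tau/(1+(omega*tau)^2); mixtures combine linearly by fractional
intensity. Calibration against a reference decay of known lifetime removes
the instrument response's rotation and demodulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ConfigurationError, InvalidInputError
from .simulate import DecayCube

__all__ = [
    "PhasorPoint",
    "PhasorField",
    "phasor_transform",
    "calibrate",
    "lifetime_to_phasor",
    "phasor_center_of_mass",
    "median_filter_phasor",
]


@dataclass(frozen=True)
class PhasorPoint:
    """A single (g, s) coordinate."""

    g: float
    s: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and np.isfinite(self.s)):
            raise InvalidInputError("phasor coordinates must be finite")

    def as_complex(self) -> complex:
        return complex(self.g, self.s)

    def distance(self, other: "PhasorPoint") -> float:
        return float(np.hypot(self.g - other.g, self.s - other.s))


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates plus photon counts.

    ``valid`` marks pixels with nonzero intensity; (g, s) are zero on
    invalid pixels rather than NaN so downstream masking stays simple.
    ``angular_frequency`` is the harmonic's omega_n = 2*pi*n/T in 1/ns.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    harmonic: int
    angular_frequency: float
    calibrated: bool = False
    valid: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.valid is None:
            self.valid = self.intensity > 0
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {a.shape for a in (self.g, self.s, self.intensity, self.valid)}
        if len(shapes) != 1:
            raise InvalidInputError("g, s, intensity, valid must share a shape")
        if self.harmonic < 1:
            raise ConfigurationError("harmonic must be >= 1")
        if self.angular_frequency <= 0:
            raise ConfigurationError("angular_frequency must be positive")
        bad = self.valid & ~(np.isfinite(self.g) & np.isfinite(self.s))
        if bad.any():
            raise InvalidInputError("non-finite phasor at valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape


def phasor_transform(cube: DecayCube, harmonic: int = 1) -> PhasorField:
    """Compute the harmonic-n phasor field of a decay cube.

    The angular frequency is inferred from the cube's time axis, taking
    the laser period as n_bins * bin_width (one full period of bins).
    """
    if harmonic < 1:
        raise ConfigurationError("harmonic must be a positive integer")
    counts = np.asarray(cube.counts, dtype=float)
    if counts.size == 0 or not np.any(counts > 0):
        raise InvalidInputError("decay cube is empty (no photons)")
    t = cube.time_axis_ns
    dt = t[1] - t[0]
    period = dt * t.size
    omega_n = 2.0 * np.pi * harmonic / period

    intensity = counts.sum(axis=2)
    valid = intensity > 0
    denom = np.where(valid, intensity, 1.0)
    cos_t = np.cos(omega_n * t)
    sin_t = np.sin(omega_n * t)
    g = np.where(valid, counts @ cos_t / denom, 0.0)
    s = np.where(valid, counts @ sin_t / denom, 0.0)
    return PhasorField(
        g=g,
        s=s,
        intensity=intensity,
        harmonic=harmonic,
        angular_frequency=omega_n,
        calibrated=False,
        meta={"channel": cube.channel, "period_ns": period},
    )


def lifetime_to_phasor(tau_ns: float, omega: float) -> PhasorPoint:
    """Closed-form universal-circle position of a mono-exponential lifetime."""
    if tau_ns < 0:
        raise InvalidInputError("tau must be >= 0")
    if omega <= 0:
        raise InvalidInputError("omega must be > 0")
    wt = omega * tau_ns
    den = 1.0 + wt * wt
    return PhasorPoint(1.0 / den, wt / den)


def calibrate(
    fieldp: PhasorField,
    reference: DecayCube,
    reference_tau_ns: float,
    harmonic: int | None = None,
) -> PhasorField:
    """Reference a phasor field against a decay of known lifetime.

    The complex rotation+scaling that maps the reference cube's mean
    measured phasor onto ``lifetime_to_phasor(reference_tau_ns, omega_n)``
    is applied to every pixel; this removes the IRF's phase delay and
    demodulation. The reference must be a uniform single-lifetime field
    acquired under the same timing.
    """
    harmonic = fieldp.harmonic if harmonic is None else harmonic
    ref_field = phasor_transform(reference, harmonic=harmonic)
    if not np.isclose(ref_field.angular_frequency, fieldp.angular_frequency):
        raise CalibrationError("reference timing does not match the field")
    w = ref_field.intensity[ref_field.valid]
    if w.sum() <= 0:
        raise CalibrationError("zero-intensity reference")
    z_meas = np.average(
        ref_field.g[ref_field.valid] + 1j * ref_field.s[ref_field.valid],
        weights=w,
    )
    if abs(z_meas) == 0:
        raise CalibrationError("reference phasor at the origin; cannot scale")
    target = lifetime_to_phasor(reference_tau_ns, fieldp.angular_frequency)
    c = target.as_complex() / z_meas
    z = (fieldp.g + 1j * fieldp.s) * c
    return replace(
        fieldp,
        g=np.where(fieldp.valid, z.real, 0.0),
        s=np.where(fieldp.valid, z.imag, 0.0),
        calibrated=True,
        meta={**fieldp.meta, "calibration_tau_ns": reference_tau_ns},
    )


def phasor_center_of_mass(
    fieldp: PhasorField, mask: np.ndarray | None = None, weighted: bool = True
) -> PhasorPoint:
    """Center of mass of the phasor distribution over a pixel mask.

    Photon-weighted by default; ``weighted=False`` gives the plain mean.
    """
    if mask is None:
        mask = np.ones(fieldp.shape, dtype=bool)
    sel = np.asarray(mask, dtype=bool) & fieldp.valid
    if not sel.any():
        raise InvalidInputError("mask selects no valid pixels")
    w = fieldp.intensity[sel] if weighted else np.ones(int(sel.sum()))
    g = float(np.average(fieldp.g[sel], weights=w))
    s = float(np.average(fieldp.s[sel], weights=w))
    return PhasorPoint(g, s)


def median_filter_phasor(fieldp: PhasorField, window: int = 3) -> PhasorField:
    """Spatial median filter on g and s; intensity is left untouched.

    Standard phasor denoising: medians preserve the phasor cloud's
    position while shrinking its spread. Window must be odd; 1 is the
    identity.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidInputError("window must be an odd integer >= 1")
    if window == 1:
        return replace(fieldp)
    g = ndimage.median_filter(fieldp.g, size=window, mode="nearest")
    s = ndimage.median_filter(fieldp.s, size=window, mode="nearest")
    return replace(
        fieldp,
        g=np.where(fieldp.valid, g, 0.0),
        s=np.where(fieldp.valid, s, 0.0),
    )
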