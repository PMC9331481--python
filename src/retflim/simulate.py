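"""Synthetic retina-section phantoms and TCSPC decay-cube simulation.

The phantom is a 2-D cross-section of a retina: stacked tissue bands
(sclera, choroid, RPE, then the retinal layers OS through RNFL), an optic
disc interrupting the retina, three vascular plexuses (deep capillaries in
the OPL, superficial capillaries at the INL/IPL junction, larger vessels
in the GCL), and two one-pixel hemoglobin bands at the basal and apical
edges of the RPE. Coordinates: pixel (0, 0) is top-left, x rightward,
y downward; physical distances in micrometres.

The forward model produces, per emission channel, a per-pixel photon-count
histogram over one laser period: a fractional-intensity-weighted sum of
single-exponential decays, periodically convolved with a Gaussian IRF,
integrated into time bins, and Poisson-sampled. Periodic (wrap-around)
convolution means incomplete decay within one period is treated exactly as
first-harmonic phasor theory assumes, so the simulated phasor of a pure
lifetime lands at the closed-form position 1/(1 - i*omega*tau) up to
time-discretization error.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidGeometryError, InvalidInputError
from .instrument import (
    FluorophoreSpec,
    InstrumentModel,
    default_emitters,
    default_fluorophores,
)

__all__ = [
    "LAYER_CODES",
    "CODE_NAMES",
    "LayerLabelMap",
    "DecayCube",
    "make_phantom",
    "layer_metabolic_profile",
    "simulate_decay_cube",
    "simulate_reference_cube",
    "component_curve",
]

#: Integer tissue codes for the label grid.
LAYER_CODES: dict[str, int] = {
    "background": 0,
    "sclera": 1,
    "choroid": 2,
    "rpe": 3,
    "os": 4,
    "is": 5,
    "onl": 6,
    "opl": 7,
    "inl": 8,
    "ipl": 9,
    "gcl": 10,
    "rnfl": 11,
    "optic_disc": 12,
    "vessel": 13,
    "rpe_basal_hb": 14,
    "rpe_apical_hb": 15,
}
CODE_NAMES: dict[int, str] = {v: k for k, v in LAYER_CODES.items()}

#: Retinal layer stack from outermost (RPE side) to innermost, excluding
#: the support tissues below the retina.
_STACK = ("sclera", "choroid", "rpe", "os", "is", "onl", "opl", "inl",
          "ipl", "gcl", "rnfl")

#: Default band thicknesses in micrometres (mouse retina scale).
DEFAULT_THICKNESS_UM: dict[str, float] = {
    "sclera": 40.0,
    "choroid": 25.0,
    "rpe": 8.0,
    "os": 25.0,
    "is": 20.0,
    "onl": 50.0,
    "opl": 12.0,
    "inl": 30.0,
    "ipl": 40.0,
    "gcl": 16.0,
    "rnfl": 10.0,
}

OUTER_CODES = tuple(LAYER_CODES[k] for k in ("os", "is", "onl"))
INNER_CODES = tuple(LAYER_CODES[k] for k in ("opl", "inl", "ipl", "gcl", "rnfl"))
RETINA_CODES = OUTER_CODES + INNER_CODES


@dataclass
class LayerLabelMap:
    """Labeled retina-section phantom.

    Attributes
    ----------
    labels:
        2-D int array (y, x), one tissue code per pixel (see LAYER_CODES).
    pixel_size_um:
        Physical pixel pitch.
    disc_position:
        (x, y) pixel coordinate of the optic-disc center on the inner
        retinal margin.
    exclusion_mask:
        Boolean (y, x) grid of pixels to drop from analysis (artifacts,
        folds). Defaults to all-False.
    section_axis:
        "superior_inferior" or "nasal_temporal"; decides how the two sides
        of the disc are named during zoning.
    """

    labels: np.ndarray
    pixel_size_um: float
    disc_position: tuple[int, int]
    exclusion_mask: np.ndarray = None  # type: ignore[assignment]
    section_axis: str = "superior_inferior"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidGeometryError("labels must be 2-D")
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(self.labels.shape, dtype=bool)
        self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
        if self.exclusion_mask.shape != self.labels.shape:
            raise InvalidGeometryError("exclusion_mask shape must match labels")
        if self.section_axis not in ("superior_inferior", "nasal_temporal"):
            raise ConfigurationError(
                f"unknown section_axis {self.section_axis!r}"
            )
        x, y = self.disc_position
        ny, nx = self.labels.shape
        if not (0 <= x < nx and 0 <= y < ny):
            raise InvalidGeometryError("disc_position outside the image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of pixels whose code is one of ``names``."""
        codes = [LAYER_CODES[n] for n in names]
        return np.isin(self.labels, codes)


@dataclass
class DecayCube:
    """Per-pixel TCSPC photon-count histograms for one emission channel.

    ``counts`` has shape (ny, nx, n_bins); integer for Poisson-sampled
    cubes, float for noiseless expectation cubes (``meta['poisson']`` says
    which). ``time_axis_ns`` holds bin centers, strictly increasing.
    """

    counts: np.ndarray
    channel: str
    time_axis_ns: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.time_axis_ns = np.asarray(self.time_axis_ns, dtype=float)
        if self.counts.ndim != 3:
            raise InvalidInputError("counts must be 3-D (y, x, t)")
        if self.counts.shape[2] != self.time_axis_ns.size:
            raise InvalidInputError("time axis length must match count bins")
        if np.any(np.diff(self.time_axis_ns) <= 0):
            raise InvalidInputError("time_axis_ns must be strictly increasing")
        if self.counts.size and self.counts.min() < 0:
            raise InvalidInputError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=2)


def _band_rows(height_px: int, thickness_px: dict[str, int]) -> dict[str, tuple[int, int]]:
    """Row span (top, bottom) of each band, stacking upward from the image
    bottom: sclera lowest, RNFL topmost tissue, background above."""
    rows: dict[str, tuple[int, int]] = {}
    bottom = height_px
    for name in _STACK:
        top = bottom - thickness_px[name]
        rows[name] = (top, bottom)
        bottom = top
    return rows


def _place_vessels(
    labels: np.ndarray,
    rng: np.random.Generator,
    center_row: int,
    radius_px: float,
    spacing_px: float,
    allowed: np.ndarray,
) -> None:
    """Stamp circular vessel lumina along a row, jittered positions."""
    ny, nx = labels.shape
    n = max(int(nx / spacing_px), 0)
    if n == 0:
        return
    base = (np.arange(n) + 0.5) * spacing_px
    xs = base + rng.uniform(-0.25 * spacing_px, 0.25 * spacing_px, size=n)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for x0 in xs:
        disk = (xx - x0) ** 2 + (yy - center_row) ** 2 <= radius_px**2
        labels[disk & allowed] = LAYER_CODES["vessel"]


def make_phantom(
    width_um: float = 600.0,
    height_um: float = 300.0,
    pixel_size_um: float = 1.0,
    layer_thicknesses: dict[str, float] | None = None,
    seed: int = 0,
    vessels: bool = True,
    vessel_spacing_um: float = 60.0,
    disc_width_um: float = 40.0,
    disc_fraction: float = 0.5,
    section_axis: str = "superior_inferior",
) -> LayerLabelMap:
    """Generate a straight (flat-mounted section) retina phantom.

    Parameters
    ----------
    width_um, height_um, pixel_size_um:
        Physical field of view and pixel pitch.
    layer_thicknesses:
        Per-band thickness in micrometres; merged over the defaults.
    vessels:
        Place the three vascular plexuses; ``False`` gives a vessel-free
        phantom.
    vessel_spacing_um:
        Mean center-to-center spacing of deep-plexus capillaries; the
        superficial plexus and GCL vessels scale from it.
    disc_width_um, disc_fraction:
        Width of the optic-disc column and its horizontal position as a
        fraction of the image width.
    """
    if width_um <= 0 or height_um <= 0 or pixel_size_um <= 0:
        raise InvalidGeometryError("dimensions and pixel size must be positive")
    th = dict(DEFAULT_THICKNESS_UM)
    if layer_thicknesses:
        unknown = set(layer_thicknesses) - set(th)
        if unknown:
            raise ConfigurationError(f"unknown layers in thicknesses: {unknown}")
        th.update(layer_thicknesses)
    if any(v <= 0 for v in th.values()):
        raise InvalidGeometryError("layer thicknesses must be positive")
    if sum(th.values()) > height_um:
        raise InvalidGeometryError("total layer thickness exceeds section height")

    nx = int(round(width_um / pixel_size_um))
    ny = int(round(height_um / pixel_size_um))
    if nx < 1 or ny < 1:
        raise InvalidGeometryError("field of view smaller than one pixel")
    th_px = {k: max(int(round(v / pixel_size_um)), 1) for k, v in th.items()}
    if sum(th_px.values()) > ny:
        raise InvalidGeometryError("rounded layer stack exceeds image height")

    rng = np.random.default_rng(seed)
    labels = np.zeros((ny, nx), dtype=np.int16)
    rows = _band_rows(ny, th_px)
    for name, (top, bottom) in rows.items():
        labels[top:bottom, :] = LAYER_CODES[name]

    # RPE hemoglobin bands: one-pixel basal (scleral side) and apical
    # (photoreceptor side) rows, when the RPE is thick enough to hold them.
    r_top, r_bottom = rows["rpe"]
    if r_bottom - r_top >= 3:
        labels[r_bottom - 1, :] = LAYER_CODES["rpe_basal_hb"]
        labels[r_top, :] = LAYER_CODES["rpe_apical_hb"]

    if vessels:
        sp = vessel_spacing_um / pixel_size_um
        retina_mask = np.isin(labels, RETINA_CODES)
        opl_mid = sum(rows["opl"]) // 2
        _place_vessels(labels, rng, opl_mid, 3.0 / pixel_size_um, sp, retina_mask)
        junction = rows["ipl"][0]  # INL/IPL boundary row
        _place_vessels(
            labels, rng, junction, 2.5 / pixel_size_um, sp * 1.3, retina_mask
        )
        gcl_mid = sum(rows["gcl"]) // 2
        _place_vessels(
            labels, rng, gcl_mid, 5.0 / pixel_size_um, sp * 3.0, retina_mask
        )

    # Optic disc: a column interrupting RPE..RNFL, centered at disc_fraction.
    x_disc = int(round(disc_fraction * nx))
    half = max(int(round(0.5 * disc_width_um / pixel_size_um)), 1)
    disc_cols = slice(max(x_disc - half, 0), min(x_disc + half, nx))
    disc_rows = slice(rows["rnfl"][0], rows["rpe"][1])
    labels[disc_rows, disc_cols] = LAYER_CODES["optic_disc"]
    disc_position = (x_disc, rows["rnfl"][0])

    return LayerLabelMap(
        labels=labels,
        pixel_size_um=pixel_size_um,
        disc_position=disc_position,
        section_axis=section_axis,
    )


def layer_metabolic_profile(
    label_map: LayerLabelMap,
    outer_bound_pct: float,
    inner_bound_pct: float,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    overrides: dict[str, float] | None = None,
) -> np.ndarray:
    """Ground-truth bound-fraction grid (percent) for the metabolic channel.

    Outer-retina pixels (OS, IS, ONL) carry ``outer_bound_pct``, inner
    pixels (OPL..RNFL) carry ``inner_bound_pct``; per-layer overrides win.
    Optional Gaussian per-pixel jitter (clipped to [0, 100]) emulates
    biological heterogeneity. Non-retina pixels carry the sentinel -1.
    """
    for name, val in (("outer_bound_pct", outer_bound_pct),
                      ("inner_bound_pct", inner_bound_pct)):
        if not 0 <= val <= 100:
            raise ConfigurationError(f"{name} must lie in [0, 100]")
    per_layer = {name: outer_bound_pct for name in ("os", "is", "onl")}
    per_layer.update(
        {name: inner_bound_pct for name in ("opl", "inl", "ipl", "gcl", "rnfl")}
    )
    if overrides:
        unknown = set(overrides) - set(LAYER_CODES)
        if unknown:
            raise ConfigurationError(f"unknown layer codes in overrides: {unknown}")
        per_layer.update(overrides)

    grid = np.full(label_map.shape, -1.0, dtype=np.float64)
    for name, pct in per_layer.items():
        grid[label_map.labels == LAYER_CODES[name]] = pct
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        retina = grid >= 0
        grid[retina] = np.clip(
            grid[retina] + rng.normal(0.0, jitter_sd, size=int(retina.sum())),
            0.0,
            100.0,
        )
    return grid


@functools.lru_cache(maxsize=256)
def _curve_cached(
    tau_ns: float,
    period_ns: float,
    n_bins: int,
    irf_fwhm_ns: float,
    irf_center_ns: float,
    oversample: int,
) -> np.ndarray:
    """Unit-area binned decay curve: wrapped exponential (or IRF pulse for
    tau == 0) circularly convolved with a wrapped Gaussian IRF."""
    n_fine = n_bins * oversample
    dt = period_ns / n_fine
    t = (np.arange(n_fine) + 0.5) * dt

    irf = _wrapped_gaussian(t, irf_center_ns, irf_fwhm_ns, period_ns)
    if tau_ns == 0.0:
        if irf is None:  # delta IRF: all photons in the center bin
            fine = np.zeros(n_fine)
            fine[int(irf_center_ns / dt) % n_fine] = 1.0
        else:
            fine = irf
    else:
        decay = np.exp(-t / tau_ns)  # wrapped exponential shape on [0, T)
        if irf is None:
            fine = decay
        else:
            fine = np.fft.irfft(np.fft.rfft(decay) * np.fft.rfft(irf), n=n_fine)
    binned = fine.reshape(n_bins, oversample).sum(axis=1)
    binned = np.clip(binned, 0.0, None)
    binned /= binned.sum()
    binned.flags.writeable = False
    return binned


def _wrapped_gaussian(
    t: np.ndarray, center: float, fwhm: float, period: float
) -> np.ndarray | None:
    """Periodically wrapped, unit-sum Gaussian; ``None`` for fwhm == 0."""
    if fwhm <= 0:
        return None
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.zeros_like(t)
    for m in (-2, -1, 0, 1, 2):
        g += np.exp(-0.5 * ((t - center + m * period) / sigma) ** 2)
    return g / g.sum()


def component_curve(
    tau_ns: float, instrument: InstrumentModel, oversample: int = 8
) -> np.ndarray:
    """Noiseless unit-area binned decay for one lifetime under ``instrument``.

    ``tau_ns == 0`` returns the binned IRF pulse (the second-harmonic
    signature)."""
    if tau_ns < 0:
        raise ConfigurationError("tau must be >= 0")
    return _curve_cached(
        float(tau_ns),
        instrument.repetition_period_ns,
        instrument.n_bins,
        instrument.irf_fwhm_ns,
        instrument.irf_center_ns,
        int(oversample),
    )


def _species_expected(
    spec: FluorophoreSpec,
    instrument: InstrumentModel,
    bound_frac: np.ndarray | None,
    oversample: int,
) -> np.ndarray:
    """Expected unit-total decay per pixel for one species.

    Returns shape (n_pixels, n_bins) when the species is metabolic (per-
    pixel bound fraction), else (n_bins,)."""
    if spec.is_shg:
        return component_curve(0.0, instrument, oversample)
    if spec.metabolic:
        if bound_frac is None:
            raise ConfigurationError(
                f"{spec.name}: metabolic species needs a ground-truth grid"
            )
        free_c = component_curve(spec.lifetimes_ns[0], instrument, oversample)
        bound_c = component_curve(spec.lifetimes_ns[1], instrument, oversample)
        f = bound_frac[:, None]
        return (1.0 - f) * free_c[None, :] + f * bound_c[None, :]
    out = np.zeros(instrument.n_bins)
    for tau, w in zip(spec.lifetimes_ns, spec.fractional_intensities):
        out += w * component_curve(tau, instrument, oversample)
    return out


def simulate_decay_cube(
    label_map: LayerLabelMap,
    instrument: InstrumentModel,
    channel: str,
    photons_per_pixel: float,
    ground_truth_pct: np.ndarray | None = None,
    fluorophores: dict[str, FluorophoreSpec] | None = None,
    emitters: dict[str, dict[str, list[tuple[str, float]]]] | None = None,
    seed: int = 0,
    poisson: bool = True,
    oversample: int = 8,
) -> DecayCube:
    """Simulate the TCSPC decay cube for one emission channel.

    Each emitting pixel's expected total count is ``photons_per_pixel``
    times the species' relative brightness; non-emitting pixels stay dark.
    Metabolic species mix their free and bound components with the
    per-pixel bound percentage from ``ground_truth_pct``.
    """
    if photons_per_pixel <= 0:
        raise InvalidInputError("photons_per_pixel must be > 0")
    instrument.channel(channel)  # raises ConfigurationError if unknown
    fluorophores = fluorophores if fluorophores is not None else default_fluorophores()
    emitters = emitters if emitters is not None else default_emitters()
    for sp in fluorophores.values():
        instrument.channel(sp.channel)

    ny, nx = label_map.shape
    nb = instrument.n_bins
    expected = np.zeros((ny, nx, nb), dtype=np.float64)

    for tissue, emission in emitters.get(channel, {}).items():
        if tissue not in LAYER_CODES:
            raise ConfigurationError(f"unknown tissue code {tissue!r} in emitters")
        mask = label_map.labels == LAYER_CODES[tissue]
        if not mask.any():
            continue
        for fluor_name, rel_brightness in emission:
            if fluor_name not in fluorophores:
                raise ConfigurationError(f"unknown fluorophore {fluor_name!r}")
            spec = fluorophores[fluor_name]
            if spec.channel != channel:
                raise ConfigurationError(
                    f"{fluor_name} emits in {spec.channel!r}, not {channel!r}"
                )
            total = photons_per_pixel * spec.brightness * rel_brightness
            if spec.metabolic:
                if ground_truth_pct is None:
                    raise ConfigurationError(
                        f"{fluor_name}: channel {channel!r} needs ground_truth_pct"
                    )
                gvals = ground_truth_pct[mask]
                if np.any(gvals < 0):
                    raise ConfigurationError(
                        f"{fluor_name}: ground truth missing (sentinel) inside "
                        f"emitting tissue {tissue!r}"
                    )
                curves = _species_expected(
                    spec, instrument, gvals / 100.0, oversample
                )
                expected[mask] += total * curves
            else:
                curve = _species_expected(spec, instrument, None, oversample)
                expected[mask] += total * curve[None, :]

    if poisson:
        rng = np.random.default_rng(seed)
        counts: np.ndarray = rng.poisson(expected).astype(np.uint32)
    else:
        counts = expected
    return DecayCube(
        counts=counts,
        channel=channel,
        time_axis_ns=instrument.time_axis_ns,
        meta={
            "pixel_size_um": label_map.pixel_size_um,
            "seed": seed,
            "poisson": poisson,
            "instrument": instrument.snapshot(),
        },
    )


def simulate_reference_cube(
    instrument: InstrumentModel,
    tau_ns: float,
    photons_per_pixel: float = 1e5,
    shape: tuple[int, int] = (16, 16),
    seed: int = 0,
    poisson: bool = True,
    oversample: int = 8,
    channel: str = "nadph",
) -> DecayCube:
    """Uniform single-lifetime field for phasor calibration.

    Emulates imaging a reference fluorophore of known lifetime with the
    same instrument; ``tau_ns == 0`` gives an IRF (second-harmonic-like)
    reference."""
    if photons_per_pixel <= 0:
        raise InvalidInputError("photons_per_pixel must be > 0")
    curve = component_curve(tau_ns, instrument, oversample)
    expected = np.broadcast_to(
        photons_per_pixel * curve, shape + (instrument.n_bins,)
    ).copy()
    if poisson:
        rng = np.random.default_rng(seed)
        counts: np.ndarray = rng.poisson(expected).astype(np.uint32)
    else:
        counts = expected
    return DecayCube(
        counts=counts,
        channel=channel,
        time_axis_ns=instrument.time_axis_ns,
        meta={
            "reference_tau_ns": tau_ns,
            "seed": seed,
            "poisson": poisson,
            "instrument": instrument.snapshot(),
        },
    )
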