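"""Instrument and fluorophore models for the TCSPC forward simulation.

The instrument model captures the handful of acquisition parameters phasor
analysis depends on: the laser repetition period (which sets the phasor
angular frequency omega = 2*pi*n/T), the number of TCSPC time bins, a
Gaussian instrument response function (IRF), and the emission channel
scheme. The default channels follow a four-band multiphoton detection
layout: NAD(P)H at 425-475 nm, FAD at 502-577 nm, hemoglobin/melanin at
600-650 nm, and collagen second-harmonic at 411-463 nm.

Fluorophores are one- or two-exponential emitters; "metabolic" species
(NAD(P)H, FAD) carry a (free, bound) lifetime pair whose per-pixel mixing
weight comes from a ground-truth bound-fraction grid rather than from a
fixed fractional-intensity table. Second-harmonic generation is effectively instantaneous and is
flagged rather than given a lifetime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "SpectralChannel",
    "InstrumentModel",
    "FluorophoreSpec",
    "default_fluorophores",
    "default_emitters",
]


@dataclass(frozen=True)
class SpectralChannel:
    """One emission detection band."""

    name: str
    band_nm: tuple[float, float]
    excitation_nm: float = 740.0

    def __post_init__(self) -> None:
        lo, hi = self.band_nm
        if not lo < hi:
            raise ConfigurationError(
                f"channel {self.name!r}: band {self.band_nm} must be (low, high)"
            )


#: Default detection scheme: metabolic autofluorescence at 740 nm excitation,
#: second harmonic at 860 nm.
DEFAULT_CHANNELS: tuple[SpectralChannel, ...] = (
    SpectralChannel("nadph", (425.0, 475.0), 740.0),
    SpectralChannel("fad", (502.0, 577.0), 740.0),
    SpectralChannel("hb_melanin", (600.0, 650.0), 740.0),
    SpectralChannel("shg", (411.0, 463.0), 860.0),
)


@dataclass(frozen=True)
class InstrumentModel:
    """TCSPC acquisition model.

    Parameters
    ----------
    repetition_period_ns:
        Laser pulse period T in ns. Default 12.5 ns (an 80 MHz Ti:sapphire
        class source).
    n_bins:
        Number of TCSPC time bins per period (>= 16).
    irf_fwhm_ns, irf_center_ns:
        Gaussian IRF full width at half maximum and center position.
    channels:
        Emission bands available on this instrument.
    """

    repetition_period_ns: float = 12.5
    n_bins: int = 256
    irf_fwhm_ns: float = 0.15
    irf_center_ns: float = 1.0
    channels: tuple[SpectralChannel, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.repetition_period_ns <= 0:
            raise ConfigurationError("repetition_period_ns must be positive")
        if self.n_bins < 16:
            raise ConfigurationError("n_bins must be >= 16")
        if not 0 <= self.irf_fwhm_ns < self.repetition_period_ns:
            raise ConfigurationError("irf_fwhm_ns must be in [0, period)")

    @property
    def bin_width_ns(self) -> float:
        return self.repetition_period_ns / self.n_bins

    @property
    def time_axis_ns(self) -> np.ndarray:
        """Bin centers in ns (length ``n_bins``)."""
        dt = self.bin_width_ns
        return (np.arange(self.n_bins) + 0.5) * dt

    def omega(self, harmonic: int = 1) -> float:
        """Angular frequency 2*pi*harmonic/T in 1/ns."""
        if harmonic < 1:
            raise ConfigurationError("harmonic must be a positive integer")
        return 2.0 * math.pi * harmonic / self.repetition_period_ns

    def channel(self, name: str) -> SpectralChannel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise ConfigurationError(
            f"channel {name!r} not in instrument "
            f"(have {[c.name for c in self.channels]})"
        )

    def snapshot(self) -> dict:
        """JSON-serializable record of the acquisition parameters."""
        return {
            "repetition_period_ns": self.repetition_period_ns,
            "n_bins": self.n_bins,
            "irf_fwhm_ns": self.irf_fwhm_ns,
            "irf_center_ns": self.irf_center_ns,
            "channels": [
                {
                    "name": c.name,
                    "band_nm": list(c.band_nm),
                    "excitation_nm": c.excitation_nm,
                }
                for c in self.channels
            ],
        }


@dataclass(frozen=True)
class FluorophoreSpec:
    """An emitting species: one or two exponential decay components.

    ``metabolic=True`` marks a free/bound pair whose mixing weight is taken
    per pixel from a ground-truth bound-percentage grid; ``lifetimes_ns``
    is then ordered (free, bound). ``is_shg=True`` marks an instantaneous
    (no-decay) species whose pulse shape is the IRF itself.
    """

    name: str
    channel: str
    lifetimes_ns: tuple[float, ...] = ()
    fractional_intensities: tuple[float, ...] = ()
    brightness: float = 1.0
    is_shg: bool = False
    metabolic: bool = False

    def __post_init__(self) -> None:
        if self.is_shg:
            if self.lifetimes_ns:
                raise ConfigurationError(
                    f"{self.name}: instantaneous species carries no lifetime"
                )
            return
        if not self.lifetimes_ns:
            raise ConfigurationError(f"{self.name}: needs >= 1 lifetime")
        if any(t <= 0 for t in self.lifetimes_ns):
            raise ConfigurationError(f"{self.name}: lifetimes must be > 0")
        if self.metabolic:
            if len(self.lifetimes_ns) != 2:
                raise ConfigurationError(
                    f"{self.name}: metabolic species needs (free, bound) lifetimes"
                )
            return  # weights come from the ground-truth grid
        fr = self.fractional_intensities
        if len(fr) != len(self.lifetimes_ns):
            raise ConfigurationError(
                f"{self.name}: fractional_intensities must match lifetimes"
            )
        if any(not 0 <= f <= 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.name}: fractional_intensities must lie in [0,1] and sum to 1"
            )


def default_fluorophores() -> dict[str, FluorophoreSpec]:
    """Default fluorophore table.

    Free NAD(P)H decays at 0.4 ns; the protein-bound lifetime is not a
    universal constant and defaults to 3.2 ns here. Free FAD decays at
    2.6 ns, bound FAD at 0.3 ns (the bound flavin is the short-lived form,
    opposite to NAD(P)H). Melanin is modelled as a short bi-exponential
    (0.1/1.0 ns, equal fractional intensities) and hemoglobin as a very
    short mono-exponential (0.05 ns), giving each a phasor position
    distinct from the others and from the second-harmonic point (1, 0).
    """
    return {
        "nadph": FluorophoreSpec(
            "nadph", "nadph", lifetimes_ns=(0.4, 3.2), metabolic=True
        ),
        "fad": FluorophoreSpec(
            "fad", "fad", lifetimes_ns=(2.6, 0.3), metabolic=True
        ),
        "melanin": FluorophoreSpec(
            "melanin",
            "hb_melanin",
            lifetimes_ns=(0.1, 1.0),
            fractional_intensities=(0.5, 0.5),
        ),
        "hemoglobin": FluorophoreSpec(
            "hemoglobin",
            "hb_melanin",
            lifetimes_ns=(0.05,),
            fractional_intensities=(1.0,),
        ),
        "collagen_shg": FluorophoreSpec("collagen_shg", "shg", is_shg=True),
    }


#: Retinal layers grouped as the analysis groups them.
OUTER_RETINA_LAYERS = ("os", "is", "onl")
INNER_RETINA_LAYERS = ("opl", "inl", "ipl", "gcl", "rnfl")
RETINA_LAYERS = OUTER_RETINA_LAYERS + INNER_RETINA_LAYERS


def default_emitters() -> dict[str, dict[str, list[tuple[str, float]]]]:
    """Default tissue -> fluorophore mapping per emission channel.

    Maps each spectral channel to ``{tissue_code_name: [(fluorophore,
    relative_brightness), ...]}``. Retinal layers emit NAD(P)H and FAD;
    vessel lumina and the two RPE hemoglobin bands emit hemoglobin; the
    RPE body and choroid emit melanin; the sclera generates second
    harmonic. No spectral bleed-through is modelled.
    """
    retina = {name: [("nadph", 1.0)] for name in RETINA_LAYERS}
    fad = {name: [("fad", 1.0)] for name in RETINA_LAYERS}
    return {
        "nadph": retina,
        "fad": fad,
        "hb_melanin": {
            "vessel": [("hemoglobin", 1.0)],
            "rpe_basal_hb": [("hemoglobin", 1.0)],
            "rpe_apical_hb": [("hemoglobin", 1.0)],
            "rpe": [("melanin", 1.0)],
            "choroid": [("melanin", 1.0)],
        },
        "shg": {"sclera": [("collagen_shg", 1.0)]},
    }
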