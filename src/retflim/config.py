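"""Pipeline configuration: a validated, YAML-loadable schema.

Every physical quantity carries its unit in the field name (``_um``,
``_ns``, ``_nm``); unknown keys are rejected so typos fail loudly. The
schema can be dumped with :func:`default_config` as a starting point.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import SchemaError
from .instrument import InstrumentModel, SpectralChannel

__all__ = [
    "InstrumentConfig",
    "PhantomConfig",
    "MetabolicTruthConfig",
    "AnalysisConfig",
    "StatsConfig",
    "PipelineConfig",
    "load_config",
    "default_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelConfig(_Strict):
    name: str
    band_nm: tuple[float, float]
    excitation_nm: float = 740.0


class InstrumentConfig(_Strict):
    repetition_period_ns: float = 12.5
    n_bins: int = 256
    irf_fwhm_ns: float = 0.15
    irf_center_ns: float = 1.0
    channels: list[ChannelConfig] = Field(
        default_factory=lambda: [
            ChannelConfig(name="nadph", band_nm=(425.0, 475.0)),
            ChannelConfig(name="fad", band_nm=(502.0, 577.0)),
            ChannelConfig(name="hb_melanin", band_nm=(600.0, 650.0)),
            ChannelConfig(name="shg", band_nm=(411.0, 463.0), excitation_nm=860.0),
        ]
    )

    def build(self) -> InstrumentModel:
        return InstrumentModel(
            repetition_period_ns=self.repetition_period_ns,
            n_bins=self.n_bins,
            irf_fwhm_ns=self.irf_fwhm_ns,
            irf_center_ns=self.irf_center_ns,
            channels=tuple(
                SpectralChannel(c.name, tuple(c.band_nm), c.excitation_nm)
                for c in self.channels
            ),
        )


class PhantomConfig(_Strict):
    # Wide enough that all five eccentricity zones fit disjointly per side:
    # mid periphery (half the disc-to-ora distance) must clear the
    # paracentral zone at 600 um, which needs ~1500 um of retina per side.
    width_um: float = 3200.0
    height_um: float = 300.0
    pixel_size_um: float = 2.0
    vessels: bool = True
    vessel_spacing_um: float = 60.0
    disc_width_um: float = 40.0
    section_axis: str = "superior_inferior"


class MetabolicTruthConfig(_Strict):
    """Ground-truth bound percentages driving the simulator."""

    nadph_outer_bound_pct: float = 58.9
    nadph_inner_bound_pct: float = 60.9
    nadph_between_image_sd: tuple[float, float] = (3.7, 2.6)
    nadph_shared_image_sd: float = 2.0
    fad_outer_free_pct: float = 75.3
    fad_inner_free_pct: float = 65.0
    jitter_sd_pct: float = 1.0


class AnalysisConfig(_Strict):
    harmonic: int = 1
    nadph_free_tau_ns: float = 0.4
    fad_free_tau_ns: float = 2.6
    calibration_tau_ns: float = 1.0
    roi_width_um: float = 150.0
    photons_per_pixel: float = 20000.0
    shg_radius: float = 0.05
    selector_radius: float = 0.05
    intensity_floor: float = 5.0
    median_filter_window: int = 1  # 1 = off


class StatsConfig(_Strict):
    grouping: str = "image"
    n_images: int = 8


class PipelineConfig(_Strict):
    seed: int = 0
    channels: list[str] = Field(
        default_factory=lambda: ["nadph", "fad", "hb_melanin", "shg"]
    )
    instrument: InstrumentConfig = Field(default_factory=InstrumentConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    truth: MetabolicTruthConfig = Field(default_factory=MetabolicTruthConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` gives the defaults."""
    data: dict = {}
    if path is not None:
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise SchemaError(f"cannot parse config {path}: {exc}") from exc
    data.update(overrides)
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise SchemaError(f"invalid configuration: {exc}") from exc


def default_config() -> PipelineConfig:
    return PipelineConfig()
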