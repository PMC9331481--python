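"""Renderings: bound-fraction rainbow maps and structural overlays."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from matplotlib import colormaps

__all__ = ["render_bound_map", "render_overlay", "STRUCTURE_COLORS"]

#: Overlay colors: pink melanin, red hemoglobin, green second harmonic.
STRUCTURE_COLORS: dict[str, tuple[int, int, int]] = {
    "melanin": (255, 105, 180),
    "hemoglobin": (255, 0, 0),
    "shg": (0, 255, 0),
}


def render_bound_map(
    bound_pct: np.ndarray,
    path: str | Path | None = None,
    vmin: float = 50.0,
    vmax: float = 70.0,
) -> np.ndarray:
    """Render a per-pixel bound-percentage map as an RGB image.

    Blue marks low bound percentage (glycolysis-leaning), red high
    (oxidative-phosphorylation-leaning); NaN pixels are black. Returns the
    uint8 RGB array and optionally writes it as TIFF.
    """
    cmap = colormaps["RdBu_r"]
    norm = np.clip((bound_pct - vmin) / (vmax - vmin), 0.0, 1.0)
    rgb = (cmap(np.nan_to_num(norm))[..., :3] * 255).astype(np.uint8)
    rgb[~np.isfinite(bound_pct)] = 0
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(Path(path), rgb, photometric="rgb")
    return rgb


def render_overlay(
    intensity: np.ndarray,
    masks: dict[str, np.ndarray],
    path: str | Path | None = None,
) -> np.ndarray:
    """Grayscale intensity base with colored structural masks on top."""
    base = intensity.astype(float)
    hi = np.percentile(base[base > 0], 99.5) if np.any(base > 0) else 1.0
    gray = (np.clip(base / max(hi, 1e-12), 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for name, mask in masks.items():
        color = STRUCTURE_COLORS.get(name, (255, 255, 0))
        rgb[np.asarray(mask, bool)] = color
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(Path(path), rgb, photometric="rgb")
    return rgb
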