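"""On-disk formats: TIFF stacks with JSON sidecars, masks, and tables.

DecayCube: multi-page TIFF (one page per time bin) + ``<stem>.json``
sidecar carrying channel, time axis, pixel size, and the instrument
snapshot. LayerLabelMap: single-page integer TIFF + JSON legend.
PhasorField: three float32 pages (g, s, intensity) + sidecar. Masks:
8-bit TIFF. Round-trips are bit-exact for integer data and float32-exact
for phasors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidInputError, SchemaError
from .phasor import PhasorField
from .simulate import CODE_NAMES, DecayCube, LayerLabelMap

__all__ = [
    "write_cube",
    "read_cube",
    "write_label_map",
    "read_label_map",
    "write_phasor_field",
    "read_phasor_field",
    "write_mask",
    "read_mask",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed sidecar {sidecar}: {exc}") from exc
    missing = [k for k in required if k not in meta]
    if missing:
        raise SchemaError(f"sidecar {sidecar} lacks required keys {missing}")
    return meta


def _read_tiff(path: Path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise InvalidInputError(f"cannot read TIFF {path}: {exc}") from exc


def _count_dtype(counts: np.ndarray) -> np.dtype:
    """Smallest unsigned integer type that holds the counts; 16-bit when
    it fits."""
    peak = counts.max(initial=0)
    return np.dtype(np.uint16 if peak <= np.iinfo(np.uint16).max else np.uint32)


def write_cube(cube: DecayCube, path: str | Path) -> Path:
    """Write a decay cube as a time-paged TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = cube.counts
    if np.issubdtype(counts.dtype, np.floating):
        data = counts.astype(np.float32)
    else:
        data = counts.astype(_count_dtype(counts))
    tifffile.imwrite(path, data.transpose(2, 0, 1))  # pages = time bins
    meta = {
        "format": "retflim.DecayCube",
        "channel": cube.channel,
        "time_axis_ns": cube.time_axis_ns.tolist(),
        "shape": list(cube.counts.shape),
        **cube.meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_cube(path: str | Path) -> DecayCube:
    path = Path(path)
    meta = _load_sidecar(path, required=("channel", "time_axis_ns", "shape"))
    pages = _read_tiff(path)
    counts = np.atleast_3d(pages).transpose(1, 2, 0)
    if list(counts.shape) != meta["shape"]:
        raise SchemaError(
            f"{path}: TIFF shape {list(counts.shape)} does not match "
            f"sidecar shape {meta['shape']}"
        )
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("format", "channel", "time_axis_ns", "shape")
    }
    return DecayCube(
        counts=counts,
        channel=meta["channel"],
        time_axis_ns=np.asarray(meta["time_axis_ns"], dtype=float),
        meta=extra,
    )


def write_label_map(label_map: LayerLabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, label_map.labels.astype(np.int16))
    meta = {
        "format": "retflim.LayerLabelMap",
        "pixel_size_um": label_map.pixel_size_um,
        "disc_position": list(label_map.disc_position),
        "section_axis": label_map.section_axis,
        "legend": {str(code): name for code, name in CODE_NAMES.items()},
        "exclusion_runs": _mask_to_runs(label_map.exclusion_mask),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_label_map(path: str | Path) -> LayerLabelMap:
    path = Path(path)
    meta = _load_sidecar(
        path, required=("pixel_size_um", "disc_position", "section_axis")
    )
    labels = _read_tiff(path)
    excl = _runs_to_mask(meta.get("exclusion_runs", []), labels.shape)
    return LayerLabelMap(
        labels=labels,
        pixel_size_um=float(meta["pixel_size_um"]),
        disc_position=tuple(meta["disc_position"]),
        exclusion_mask=excl,
        section_axis=meta["section_axis"],
    )


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Row-wise run-length encoding of a boolean mask (compact JSON)."""
    runs = []
    for y, row in enumerate(np.asarray(mask, dtype=bool)):
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row, [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            runs.append([int(y), int(start), int(stop)])
    return runs


def _runs_to_mask(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for y, start, stop in runs:
        mask[y, start:stop] = True
    return mask


def write_phasor_field(fieldp: PhasorField, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack(
        [
            fieldp.g.astype(np.float32),
            fieldp.s.astype(np.float32),
            fieldp.intensity.astype(np.float32),
        ]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "format": "retflim.PhasorField",
        "harmonic": fieldp.harmonic,
        "angular_frequency": fieldp.angular_frequency,
        "calibrated": fieldp.calibrated,
        **{k: v for k, v in fieldp.meta.items() if _jsonable(v)},
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_phasor_field(path: str | Path) -> PhasorField:
    path = Path(path)
    meta = _load_sidecar(path, required=("harmonic", "angular_frequency"))
    stack = _read_tiff(path)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise SchemaError(f"{path}: expected 3 pages (g, s, intensity)")
    g, s, intensity = (stack[i].astype(float) for i in range(3))
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("format", "harmonic", "angular_frequency", "calibrated")
    }
    return PhasorField(
        g=g,
        s=s,
        intensity=intensity,
        harmonic=int(meta["harmonic"]),
        angular_frequency=float(meta["angular_frequency"]),
        calibrated=bool(meta.get("calibrated", False)),
        meta=extra,
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return _read_tiff(Path(path)) > 0


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
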