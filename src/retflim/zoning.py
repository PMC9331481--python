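"""Eccentricity zones, outer/inner layer regions, and fixed-width ROIs.

A retina section is split at the optic disc into two sides (superior vs
inferior for vertical sections, nasal vs temporal for horizontal ones) and
each side into five eccentricity zones measured along the retinal midline:
peripapillary (200 um from the disc), central (400 um), paracentral
(600 um), mid periphery (halfway from disc to ora serrata), and far
periphery (at the ora serrata, pulled in by half an ROI width so the ROI
fits). Each zone holds one outer-retina ROI (OS + IS + ONL) and one
inner-retina ROI (OPL through RNFL) of fixed width, 150 um by default; the
RPE belongs to neither region.

Eccentricity is arc length along the retina midline by default (straight
phantoms make this identical to horizontal distance); a Euclidean option
exists for comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, InvalidInputError
from .simulate import (
    INNER_CODES,
    LAYER_CODES,
    OUTER_CODES,
    RETINA_CODES,
    LayerLabelMap,
)

logger = logging.getLogger(__name__)

__all__ = ["ZONES", "ZoneMap", "ROI", "ROISet", "build_zones", "make_rois"]

#: Zone names and the order fixed-distance zones claim columns in.
ZONES = ("peripapillary", "central", "paracentral", "mid_periphery", "far_periphery")
ZONE_CODES = {name: i + 1 for i, name in enumerate(ZONES)}

_SIDE_NAMES = {
    "superior_inferior": ("superior", "inferior"),
    "nasal_temporal": ("nasal", "temporal"),
}

REGION_NONE, REGION_OUTER, REGION_INNER = 0, 1, 2


@dataclass
class ZoneMap:
    """Per-pixel zone/region/side labels plus the zone-center geometry.

    ``zone_labels`` uses ZONE_CODES (0 = none); ``region_labels`` uses
    0/1/2 = none/outer/inner; ``side_labels`` 0/1/2 = none/first/second
    side per the section axis. ``zone_centers`` maps (zone, side_name) to
    the zone center's arc distance from the disc in micrometres;
    ``column_arc_um`` holds each column's signed arc distance (negative on
    the first side).
    """

    zone_labels: np.ndarray
    region_labels: np.ndarray
    side_labels: np.ndarray
    zone_centers: dict[tuple[str, str], float]
    column_arc_um: np.ndarray
    side_names: tuple[str, str]
    pixel_size_um: float
    label_map: LayerLabelMap

    def zone_mask(self, zone: str, side: str | None = None) -> np.ndarray:
        m = self.zone_labels == ZONE_CODES[zone]
        if side is not None:
            m &= self.side_labels == (self.side_names.index(side) + 1)
        return m


@dataclass
class ROI:
    """One fixed-width analysis region."""

    roi_id: str
    mask: np.ndarray
    zone: str
    region: str
    side: str
    width_um: float

    @property
    def n_pixels(self) -> int:
        return int(np.asarray(self.mask).sum())


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def get(self, roi_id: str) -> ROI:
        for r in self.rois:
            if r.roi_id == roi_id:
                return r
        raise KeyError(roi_id)


def _retina_columns(labels: np.ndarray) -> np.ndarray:
    """Columns containing analysable retina (outer or inner region layers)."""
    region = np.isin(labels, OUTER_CODES + INNER_CODES)
    return region.any(axis=0)


def _midline(labels: np.ndarray) -> np.ndarray:
    """Per-column midline row: midpoint of the region-layer envelope
    (robust to vessel lumina inside the band); NaN columns (disc, gaps)
    are linearly interpolated so arc length accumulates smoothly."""
    region = np.isin(labels, OUTER_CODES + INNER_CODES)
    nx = labels.shape[1]
    mid = np.full(nx, np.nan)
    has = region.any(axis=0)
    if not has.any():
        raise InvalidGeometryError("no retina in the label map")
    top = np.argmax(region, axis=0)
    bottom = labels.shape[0] - 1 - np.argmax(region[::-1], axis=0)
    mid[has] = 0.5 * (top[has] + bottom[has])
    cols = np.flatnonzero(has)
    mid = np.interp(np.arange(nx), cols, mid[cols])
    return mid


def build_zones(
    label_map: LayerLabelMap,
    roi_width_um: float = 150.0,
    distance: str = "arc",
) -> ZoneMap:
    """Partition a labeled section into eccentricity zones and regions.

    Fixed-eccentricity zone centers sit 200/400/600 um from the optic disc
    along the midline; mid periphery at half the disc-to-ora distance, far
    periphery half an ROI width in from the ora serrata. Fixed-distance
    zones take precedence where a short retina would make zones overlap;
    displaced zones are dropped with a warning.
    """
    if distance not in ("arc", "euclidean"):
        raise InvalidInputError("distance must be 'arc' or 'euclidean'")
    labels = label_map.labels
    ny, nx = labels.shape
    px = label_map.pixel_size_um
    half = roi_width_um / 2.0

    x_disc, y_disc = label_map.disc_position
    disc_cols = (labels == LAYER_CODES["optic_disc"]).any(axis=0)
    tissue_cols = _retina_columns(labels) | disc_cols
    if not (disc_cols.any() or tissue_cols[x_disc]):
        raise InvalidGeometryError("optic disc does not lie inside tissue")

    mid = _midline(labels)
    # Arc length along the midline, accumulated column by column.
    dy = np.diff(mid)
    if distance == "arc":
        step = np.sqrt(1.0 + dy**2) * px
    else:
        step = np.full(nx - 1, px)
    cum = np.concatenate([[0.0], np.cumsum(step)])
    arc = cum - cum[x_disc]  # signed distance from the disc column

    side_labels = np.zeros((ny, nx), dtype=np.int8)
    region_labels = np.zeros((ny, nx), dtype=np.int8)
    region_labels[np.isin(labels, OUTER_CODES)] = REGION_OUTER
    region_labels[np.isin(labels, INNER_CODES)] = REGION_INNER

    zone_labels = np.zeros((ny, nx), dtype=np.int8)
    zone_centers: dict[tuple[str, str], float] = {}
    side_names = _SIDE_NAMES[label_map.section_axis]

    retina_cols = _retina_columns(labels)
    for side_idx, sign in ((0, -1.0), (1, +1.0)):
        side_name = side_names[side_idx]
        dist = sign * arc  # positive going outward on this side
        on_side = (dist > 0) & retina_cols
        side_labels[:, on_side] = side_idx + 1
        if not on_side.any():
            warnings.warn(f"no retina on the {side_name} side of the disc")
            continue
        ora_um = float(dist[on_side].max())
        centers = {
            "peripapillary": 200.0,
            "central": 400.0,
            "paracentral": 600.0,
            "mid_periphery": ora_um / 2.0,
            "far_periphery": ora_um - half,
        }
        claimed = np.zeros(nx, dtype=bool)
        for zone in ZONES:
            c = centers[zone]
            cols = on_side & (dist >= c - half) & (dist < c + half)
            if not cols.any() or c - half < 0 or c + half > ora_um + px:
                warnings.warn(
                    f"zone {zone!r} does not fit on the {side_name} side; omitted"
                )
                continue
            if (cols & claimed).any():
                warnings.warn(
                    f"zone {zone!r} overlaps an earlier zone on the "
                    f"{side_name} side; omitted"
                )
                continue
            claimed |= cols
            zone_labels[:, cols] = ZONE_CODES[zone]
            zone_centers[(zone, side_name)] = c
    # Zones only exist where retina does.
    zone_labels[~np.isin(labels, RETINA_CODES)] = 0
    return ZoneMap(
        zone_labels=zone_labels,
        region_labels=region_labels,
        side_labels=side_labels,
        zone_centers=zone_centers,
        column_arc_um=arc,
        side_names=side_names,
        pixel_size_um=px,
        label_map=label_map,
    )


def make_rois(zone_map: ZoneMap, width_um: float = 150.0) -> ROISet:
    """Emit one outer and one inner ROI per (zone, side).

    ROIs are ``width_um`` wide, centered on the zone center along the
    midline, clipped to tissue and minus the exclusion mask; ROIs emptied
    by clipping are dropped with a log entry.
    """
    if width_um <= 0:
        raise InvalidInputError("ROI width must be positive")
    half = width_um / 2.0
    lm = zone_map.label_map
    excl = lm.exclusion_mask
    out = ROISet()
    for (zone, side), center in sorted(zone_map.zone_centers.items()):
        sign = -1.0 if side == zone_map.side_names[0] else 1.0
        dist = sign * zone_map.column_arc_um
        cols = (dist >= center - half) & (dist < center + half)
        for region, code in (("outer", REGION_OUTER), ("inner", REGION_INNER)):
            mask = cols[None, :] & (zone_map.region_labels == code) & ~excl
            roi_id = f"{zone}_{side}_{region}"
            if not mask.any():
                logger.info("ROI %s empty after clipping; dropped", roi_id)
                continue
            out.rois.append(
                ROI(
                    roi_id=roi_id,
                    mask=mask,
                    zone=zone,
                    region=region,
                    side=side,
                    width_um=width_um,
                )
            )
    return out
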