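"""Accessible-area (M) construction from altitude, synanthropy and dispersal.

The calibration region M is the area hypothesized to have been reachable
by the species.  It is assembled from three criteria:

1. an altitude band applied to the DEM (the species' reported
   altitudinal range, inclusive at both ends);
2. a synanthropy band applied to the Human Influence Index grid, derived
   from the HII values observed at the occurrence records according to
   the species' synanthropy class — asynanthropic species (which avoid
   humans) keep HII from the index floor 0 up to the observed maximum,
   eusynanthropic species (attracted to humans) keep from the observed
   minimum up to the index ceiling 64, and hemisynanthropic species keep
   the observed range;
3. a dispersal buffer of the species' flight range (default 4.8 km, the
   minimum known flight range of the Calliphoridae family) around every
   occurrence.

By default M = (altitude mask AND HII mask) OR buffer, which guarantees
every occurrence stays inside its own calibration region; the
intersection rule is available via ``combine_rule="env_intersect_buffer"``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .landscape import LandscapeStack
from .occurrences import OccurrenceSet, haversine_km

__all__ = [
    "SpeciesProfile",
    "AccessibleArea",
    "altitude_mask",
    "synanthropy_band",
    "hii_mask",
    "dispersal_buffer",
    "build_M",
    "build_accessible_area",
]

#: Minimum known flight range of the Calliphoridae family, km.
DEFAULT_DISPERSAL_KM = 4.8

SYNANTHROPY_CLASSES = ("asynanthropic", "hemisynanthropic", "eusynanthropic")


@dataclasses.dataclass(frozen=True)
class SpeciesProfile:
    """Per-species M-construction criteria."""

    species: str
    altitude_band: tuple[float, float]
    synanthropy_class: str
    dispersal_km: float = DEFAULT_DISPERSAL_KM

    def __post_init__(self) -> None:
        if self.altitude_band[0] >= self.altitude_band[1]:
            raise ValueError("altitude band min must be < max")
        if self.dispersal_km <= 0:
            raise ValueError("dispersal_km must be > 0")
        if self.synanthropy_class not in SYNANTHROPY_CLASSES:
            raise ValueError(
                f"synanthropy_class must be one of {SYNANTHROPY_CLASSES}"
            )


@dataclasses.dataclass
class AccessibleArea:
    """The accessible-area mask and its components."""

    mask: np.ndarray
    hii_band_used: tuple[float, float]
    altitude_component: np.ndarray
    hii_component: np.ndarray
    buffer_component: np.ndarray
    combine_rule: str = "env_union_buffer"

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def altitude_mask(stack: LandscapeStack, band: tuple[float, float]) -> np.ndarray:
    """Cells whose DEM value falls in ``band`` (inclusive both ends)."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("altitude band min must be < max")
    mask = (stack.dem >= lo) & (stack.dem <= hi) & ~stack.nodata_mask
    if not mask.any():
        raise ValueError(
            f"altitude band ({lo}, {hi}) selects no cells of the DEM "
            f"(range {stack.dem[~stack.nodata_mask].min():.0f}-"
            f"{stack.dem[~stack.nodata_mask].max():.0f} m)"
        )
    return mask


def synanthropy_band(
    stack: LandscapeStack, occ: OccurrenceSet, cls: str
) -> tuple[float, float]:
    """HII band implied by the occurrences under a synanthropy class.

    Let v be the HII values at the occurrence cells: asynanthropic ->
    (0, max v); eusynanthropic -> (min v, 64); hemisynanthropic ->
    (min v, max v).
    """
    if cls not in SYNANTHROPY_CLASSES:
        raise ValueError(f"unknown synanthropy class {cls!r}")
    if len(occ) == 0:
        raise ValueError("occurrence set is empty")
    vals = []
    for rid, lon, lat in occ.records:
        r, c = stack.cell_of(lon, lat)
        if stack.nodata_mask[r, c]:
            raise ValueError(f"record {rid!r} falls on a nodata HII cell")
        vals.append(stack.hii[r, c])
    v = np.array(vals)
    if cls == "asynanthropic":
        return (0.0, float(v.max()))
    if cls == "eusynanthropic":
        return (float(v.min()), 64.0)
    return (float(v.min()), float(v.max()))


def hii_mask(stack: LandscapeStack, band: tuple[float, float]) -> np.ndarray:
    """Cells whose HII value falls in ``band`` (inclusive both ends)."""
    lo, hi = band
    if not (0 <= lo <= hi <= 64):
        raise ValueError("HII band must satisfy 0 <= min <= max <= 64")
    return (stack.hii >= lo) & (stack.hii <= hi) & ~stack.nodata_mask


def dispersal_buffer(
    stack: LandscapeStack, occ: OccurrenceSet, radius: float
) -> np.ndarray:
    """Cells whose center lies within ``radius`` km of any occurrence.

    Distances are great-circle from each cell center to the exact point
    coordinates (no rasterized polygon intermediary), so every
    occurrence's own cell is always inside the buffer.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(occ) == 0:
        raise ValueError("occurrence set is empty")
    rows, cols = np.indices(stack.shape)
    lon_c, lat_c = stack.cell_center(rows.ravel(), cols.ravel())
    within = np.zeros(stack.n_rows * stack.n_cols, dtype=bool)
    for _, lon, lat in occ.records:
        d = haversine_km(lon_c, lat_c, lon, lat)
        within |= d <= radius
    # occurrence cells are inside by construction (distance to own center
    # is at most half a cell diagonal < any positive radius at these cell
    # sizes), but enforce it explicitly for tiny radii
    for r, c in occ.cells(stack):
        within[r * stack.n_cols + c] = True
    return (within.reshape(stack.shape)) & ~stack.nodata_mask


def build_M(
    altitude: np.ndarray,
    hii: np.ndarray,
    buffer: np.ndarray,
    combine_rule: str = "env_union_buffer",
    hii_band_used: tuple[float, float] = (0.0, 64.0),
) -> AccessibleArea:
    """Combine the three component masks into the accessible area.

    ``env_union_buffer`` (default): M = (altitude AND hii) OR buffer.
    ``env_intersect_buffer``: M = (altitude AND hii) AND buffer.
    """
    if combine_rule not in ("env_union_buffer", "env_intersect_buffer"):
        raise ValueError(f"unknown combine_rule {combine_rule!r}")
    env = altitude & hii
    mask = (env | buffer) if combine_rule == "env_union_buffer" else (env & buffer)
    if not mask.any():
        raise ValueError("accessible area is empty under the requested rule")
    return AccessibleArea(
        mask=mask,
        hii_band_used=hii_band_used,
        altitude_component=altitude,
        hii_component=hii,
        buffer_component=buffer,
        combine_rule=combine_rule,
    )


def build_accessible_area(
    stack: LandscapeStack,
    occ: OccurrenceSet,
    profile: SpeciesProfile,
    combine_rule: str = "env_union_buffer",
) -> AccessibleArea:
    """Full M construction for one species from its profile and records."""
    alt = altitude_mask(stack, profile.altitude_band)
    band = synanthropy_band(stack, occ, profile.synanthropy_class)
    hii = hii_mask(stack, band)
    buf = dispersal_buffer(stack, occ, profile.dispersal_km)
    return build_M(alt, hii, buf, combine_rule=combine_rule, hii_band_used=band)
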