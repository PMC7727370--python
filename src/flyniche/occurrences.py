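"""Occurrence records: containers, CSV I/O, spatial thinning, value extraction.

Presence records are species-tagged lon/lat points (WGS84 decimal
degrees) with provenance ids.  Spatial thinning removes near-duplicate
localities (museum pseudo-replicates) before modelling; value extraction
reads the containing cell of each point from a raster stack.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape import LandscapeStack

__all__ = [
    "OccurrenceSet",
    "thin_occurrences",
    "extract_env_at_points",
    "haversine_km",
    "read_occurrences",
    "write_occurrences",
]

#: Mean Earth radius, km (IUGG).
EARTH_RADIUS_KM = 6371.0088


@dataclasses.dataclass
class OccurrenceSet:
    """Ordered presence records for one species.

    ``records`` is a list of ``(record_id, lon, lat)`` tuples; ids are
    unique, longitudes in [-180, 180], latitudes in [-90, 90].
    """

    species: str
    records: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record_ids must be unique")
        for rid, lon, lat in self.records:
            if not (-180 <= lon <= 180):
                raise ValueError(f"record {rid}: longitude {lon} out of range")
            if not (-90 <= lat <= 90):
                raise ValueError(f"record {rid}: latitude {lat} out of range")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def lats(self) -> np.ndarray:
        return np.array([r[2] for r in self.records])

    @property
    def record_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def subset(self, indices: Sequence[int]) -> "OccurrenceSet":
        return OccurrenceSet(self.species, [self.records[i] for i in indices])

    def cells(self, stack: LandscapeStack) -> list[tuple[int, int]]:
        """Row/col of the containing cell for every record."""
        return [stack.cell_of(lon, lat) for _, lon, lat in self.records]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(occ: OccurrenceSet, min_distance: float) -> OccurrenceSet:
    """Greedy spatial thinning by great-circle distance.

    Records are scanned in input order; a record is retained iff it lies
    strictly farther than ``min_distance`` km from every previously
    retained record.  ``min_distance = 0`` removes only exact coordinate
    duplicates.  Thinning an already-thinned set is a no-op.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    if len(occ) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    kept: list[int] = []
    for i, (rid, lon, lat) in enumerate(occ.records):
        if min_distance == 0:
            dup = any(
                occ.records[j][1] == lon and occ.records[j][2] == lat for j in kept
            )
            if not dup:
                kept.append(i)
            continue
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(
            lon, lat, [occ.records[j][1] for j in kept], [occ.records[j][2] for j in kept]
        )
        if np.all(d > min_distance):
            kept.append(i)
    return occ.subset(kept)


def extract_env_at_points(
    stack: LandscapeStack,
    points: OccurrenceSet,
    layer_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Value table at occurrence points (one row per point, column per layer).

    Values are read from the containing cell (cell-center registration,
    point-in-cell lookup).  Rows align with record order; the index is
    the record id.  Layer names may include ``"dem"`` and ``"hii"``.
    """
    if layer_names is None:
        layer_names = stack.layer_names
    grids = {}
    for name in layer_names:
        if name == "dem":
            grids[name] = stack.dem
        elif name == "hii":
            grids[name] = stack.hii
        elif name in stack.env_layers:
            grids[name] = stack.env_layers[name]
        else:
            raise KeyError(f"layer {name!r} not in stack")
    rows = []
    for rid, lon, lat in points.records:
        r, c = stack.cell_of(lon, lat)
        if stack.nodata_mask[r, c]:
            raise ValueError(f"record {rid!r} falls on a nodata cell ({r}, {c})")
        rows.append([grids[n][r, c] for n in layer_names])
    return pd.DataFrame(rows, columns=list(layer_names), index=points.record_ids)


# -- CSV I/O --------------------------------------------------------------


def read_occurrences(path: str | Path) -> dict[str, OccurrenceSet]:
    """Read a `species,longitude,latitude[,record_id]` CSV into per-species sets.

    Missing record_ids are autogenerated from row numbers; malformed
    coordinates are rejected with their line number.
    """
    df = pd.read_csv(path, dtype={"species": str})
    required = {"species", "longitude", "latitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    if "record_id" not in df.columns:
        df["record_id"] = [f"row-{i + 2}" for i in range(len(df))]  # header = line 1
    for i, row in df.iterrows():
        line = i + 2
        if not (-180 <= row["longitude"] <= 180) or not (-90 <= row["latitude"] <= 90):
            raise ValueError(
                f"{path} line {line}: coordinates out of range "
                f"({row['longitude']}, {row['latitude']})"
            )
    if df["record_id"].duplicated().any():
        dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
        raise ValueError(f"{path}: duplicated record_id {dup!r}")
    out = {}
    for sp, grp in df.groupby("species", sort=False):
        out[sp] = OccurrenceSet(
            species=sp,
            records=[
                (str(r.record_id), float(r.longitude), float(r.latitude))
                for r in grp.itertuples()
            ],
        )
    return out


def write_occurrences(path: str | Path, sets: Iterable[OccurrenceSet]) -> None:
    frames = [
        pd.DataFrame(
            {
                "species": occ.species,
                "longitude": occ.lons,
                "latitude": occ.lats,
                "record_id": occ.record_ids,
            }
        )
        for occ in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
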