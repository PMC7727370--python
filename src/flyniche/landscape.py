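"""Co-registered raster stacks and synthetic landscape generation.

The analysis operates on a stack of co-registered WGS84 grids: a digital
elevation model (DEM, metres), a Human Influence Index grid (HII, a 0-64
index of human impact) and a set of continuous environmental layers
(bioclimatic variables in the real application).  :class:`LandscapeStack`
is the in-memory container; :func:`generate_landscape` and
:func:`generate_species` produce synthetic stacks and occurrence records
with the statistical structure the downstream analysis assumes —
spatially autocorrelated environmental fields, a wide-spanning DEM, and
species sampled from a known log-linear suitability surface restricted
to an altitude band and a synanthropy (HII) band.

Rasters are read and written as ESRI ASCII grids (plain text ``.asc``)
with a JSON manifest tying the layers of a stack together.  Grids are
north-up with cell-center registration: the cell at (row 0, col 0) is
the north-west corner, and coordinates refer to cell centers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LandscapeStack",
    "SyntheticSpeciesTruth",
    "generate_landscape",
    "generate_species",
    "draw_occurrence_cells",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Default value ranges used when rescaling synthetic fields.
DEM_RANGE = (0.0, 4000.0)
HII_RANGE = (0.0, 64.0)
ENV_RANGE = (0.0, 1.0)


@dataclasses.dataclass
class LandscapeStack:
    """Co-registered grids sharing one geotransform.

    Parameters
    ----------
    origin_lon, origin_lat
        Coordinates (decimal degrees, WGS84) of the *outer corner* of the
        north-west cell; cell centers sit half a cell inward.
    cell_size
        Cell edge length in degrees (square cells, north-up).
    dem
        Elevation grid in metres.
    hii
        Human Influence Index grid (0-64, unitless).
    env_layers
        Ordered mapping of layer name -> 2-D float grid.
    nodata_mask
        Boolean grid, ``True`` where *all* layers are nodata.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    dem: np.ndarray
    hii: np.ndarray
    env_layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.n_rows, self.n_cols)
        grids = {"dem": self.dem, "hii": self.hii, "nodata_mask": self.nodata_mask}
        grids.update(self.env_layers)
        for name, g in grids.items():
            if g.shape != shape:
                raise ValueError(
                    f"layer {name!r} has shape {g.shape}, expected {shape}"
                )
        valid = ~self.nodata_mask
        if valid.any():
            d = self.dem[valid]
            if d.min() < 0 or d.max() > 9000:
                raise ValueError("dem values must lie in [0, 9000] m")
            h = self.hii[valid]
            if h.min() < 0 or h.max() > 64:
                raise ValueError("hii values must lie in [0, 64]")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def layer_names(self) -> list[str]:
        return list(self.env_layers)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int):
        """Lon/lat of cell centers (north-up, cell-center registration)."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) is outside the landscape extent")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        try:
            self.cell_of(lon, lat)
        except ValueError:
            return False
        return True

    # -- I/O --------------------------------------------------------------

    def to_dir(self, path: str | Path) -> Path:
        """Write the stack as one ``.asc`` per layer plus ``manifest.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        names = []
        for name, grid in [("dem", self.dem), ("hii", self.hii)] + list(
            self.env_layers.items()
        ):
            write_ascii_grid(
                path / f"{name}.asc", grid, self, nodata_mask=self.nodata_mask
            )
            names.append(name)
        manifest = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "cell_size": self.cell_size,
            "crs": "EPSG:4326",
            "dem": "dem.asc",
            "hii": "hii.asc",
            "env_layers": {n: f"{n}.asc" for n in self.layer_names},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "LandscapeStack":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        ref = None
        grids: dict[str, np.ndarray] = {}
        masks = []
        for name, fname in [("dem", manifest["dem"]), ("hii", manifest["hii"])] + [
            (n, f) for n, f in manifest["env_layers"].items()
        ]:
            grid, header = read_ascii_grid(path / fname)
            if ref is None:
                ref = header
            elif header != ref:
                raise ValueError(
                    f"layer {name!r} geotransform {header} does not match {ref}"
                )
            masks.append(np.isnan(grid))
            grids[name] = grid
        nodata = masks[0]
        for m in masks[1:]:
            nodata = nodata | m
        env = {n: grids[n] for n in manifest["env_layers"]}
        return cls(
            n_rows=manifest["n_rows"],
            n_cols=manifest["n_cols"],
            origin_lon=manifest["origin_lon"],
            origin_lat=manifest["origin_lat"],
            cell_size=manifest["cell_size"],
            dem=np.where(nodata, 0.0, grids["dem"]),
            hii=np.where(nodata, 0.0, grids["hii"]),
            env_layers={n: np.where(nodata, 0.0, g) for n, g in env.items()},
            nodata_mask=nodata,
        )


@dataclasses.dataclass(frozen=True)
class SyntheticSpeciesTruth:
    """Generative truth of a synthetic species.

    ``true_coefficients`` are per-layer weights of the log-linear
    suitability ``exp(sum_k w_k * env_k(x))``; sampling is restricted to
    cells whose elevation falls in ``altitude_band`` and whose HII falls
    in ``hii_band`` (both inclusive).
    """

    true_coefficients: Mapping[str, float]
    altitude_band: tuple[float, float]
    synanthropy_class: str = "hemisynanthropic"
    hii_band: tuple[float, float] = (0.0, 64.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.altitude_band[0] >= self.altitude_band[1]:
            raise ValueError("altitude_band min must be < max")
        if not (0 <= self.hii_band[0] <= self.hii_band[1] <= 64):
            raise ValueError("hii_band must lie within [0, 64]")
        if self.synanthropy_class not in (
            "asynanthropic",
            "hemisynanthropic",
            "eusynanthropic",
        ):
            raise ValueError(f"unknown synanthropy class {self.synanthropy_class!r}")


# -- synthetic generation -------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape, autocorr_length: float):
    """Spatially autocorrelated standard field: smoothed white noise.

    White noise convolved with an isotropic Gaussian kernel whose sigma is
    the requested correlation length, then standardized to zero mean and
    unit variance over the grid.
    """
    field = rng.standard_normal(shape)
    if autocorr_length > 0:
        field = ndimage.gaussian_filter(field, sigma=autocorr_length, mode="reflect")
    field = field - field.mean()
    sd = field.std()
    if sd == 0:  # pathological tiny grid; keep the constant field
        return field
    return field / sd


def _rescale(field: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field.min(), field.max()
    if fmax == fmin:
        return np.full_like(field, (lo + hi) / 2)
    return lo + (field - fmin) * (hi - lo) / (fmax - fmin)


def generate_landscape(
    n_rows: int,
    n_cols: int,
    n_env: int,
    autocorr_length: float = 8.0,
    forced_pair_correlation: float | None = None,
    seed: int = 0,
    origin_lon: float = -75.0,
    origin_lat: float = 5.0,
    cell_size: float = 1.0 / 120.0,
) -> LandscapeStack:
    """Generate a synthetic landscape stack.

    Environmental layers are smooth (spatially autocorrelated) random
    fields rescaled to [0, 1]; the DEM spans [0, 4000] m and the HII grid
    spans [0, 64].  When ``forced_pair_correlation`` is given, the first
    two environmental layers are mixed so that their empirical Pearson
    correlation over the grid equals the requested value (the second
    field is first decorrelated against the first using the realized
    sample correlation, then remixed at the target weight).

    Identical seeds produce bit-identical stacks.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("n_rows and n_cols must be >= 8")
    if n_env < 1:
        raise ValueError("n_env must be >= 1")
    if forced_pair_correlation is not None:
        if abs(forced_pair_correlation) > 1:
            raise ValueError("|forced_pair_correlation| must be <= 1")
        if n_env < 2:
            raise ValueError("forced_pair_correlation requires n_env >= 2")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    fields = [_smooth_field(rng, shape, autocorr_length) for _ in range(n_env)]

    if forced_pair_correlation is not None:
        r = forced_pair_correlation
        a, b = fields[0], fields[1]
        # Gram-Schmidt against the realized field so the *empirical*
        # correlation hits r, not just the population correlation.
        rho = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
        b_perp = b - rho * a
        sd = b_perp.std()
        if sd > 0:
            b_perp = (b_perp - b_perp.mean()) / sd
        fields[1] = r * a + np.sqrt(max(0.0, 1 - r * r)) * b_perp

    env = {
        f"env_{i + 1}": _rescale(f, *ENV_RANGE) for i, f in enumerate(fields)
    }
    dem = _rescale(_smooth_field(rng, shape, autocorr_length), *DEM_RANGE)
    hii = _rescale(_smooth_field(rng, shape, autocorr_length), *HII_RANGE)
    nodata = np.zeros(shape, dtype=bool)
    return LandscapeStack(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        cell_size=cell_size,
        dem=dem,
        hii=hii,
        env_layers=env,
        nodata_mask=nodata,
    )


def _eligible_cells(stack: LandscapeStack, truth: SyntheticSpeciesTruth):
    lo_a, hi_a = truth.altitude_band
    lo_h, hi_h = truth.hii_band
    eligible = (
        (stack.dem >= lo_a)
        & (stack.dem <= hi_a)
        & (stack.hii >= lo_h)
        & (stack.hii <= hi_h)
        & ~stack.nodata_mask
    )
    return np.flatnonzero(eligible.ravel())


def true_suitability(stack: LandscapeStack, truth: SyntheticSpeciesTruth):
    """Unnormalized log-linear suitability exp(w . env) on every cell."""
    log_s = np.zeros(stack.shape)
    for name, w in truth.true_coefficients.items():
        log_s += w * stack.env_layers[name]
    return np.exp(log_s)


def draw_occurrence_cells(
    stack: LandscapeStack,
    truth: SyntheticSpeciesTruth,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flat cell indices drawn *with replacement*, prob proportional to suitability.

    This is the raw multinomial sampling step underneath
    :func:`generate_species`; exposed so the sampling distribution itself
    can be checked before duplicate collapse.
    """
    flat = _eligible_cells(stack, truth)
    if flat.size == 0:
        raise ValueError("no cells satisfy the altitude and HII bands")
    weights = true_suitability(stack, truth).ravel()[flat]
    p = weights / weights.sum()
    return flat[rng.choice(flat.size, size=n_draws, replace=True, p=p)]


def generate_species(
    stack: LandscapeStack,
    truth: SyntheticSpeciesTruth,
    n_occurrences: int,
    species: str = "synthetic_species",
):
    """Sample occurrence records from the generative suitability.

    Cells are drawn with replacement with probability proportional to
    ``exp(true_coefficients . env)`` over the eligible region (altitude
    and HII bands, inclusive); duplicate cell draws are collapsed and
    sampling repeats until ``n_occurrences`` distinct cells are obtained
    (museum records are effectively one per locality).  Occurrences are
    placed at cell centers.  Identical seeds give identical sets.
    """
    from .occurrences import OccurrenceSet

    if n_occurrences < 1:
        raise ValueError("n_occurrences must be >= 1")
    flat = _eligible_cells(stack, truth)
    if flat.size == 0:
        raise ValueError("no cells satisfy the altitude and HII bands")
    if flat.size < n_occurrences:
        raise ValueError(
            f"only {flat.size} eligible cells for {n_occurrences} distinct occurrences"
        )
    rng = np.random.default_rng(truth.seed)
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < n_occurrences:
        batch = draw_occurrence_cells(stack, truth, n_occurrences, rng)
        for c in batch:
            c = int(c)
            if c not in seen:
                seen.add(c)
                chosen.append(c)
                if len(chosen) == n_occurrences:
                    break
    rows, cols = np.unravel_index(np.array(chosen), stack.shape)
    lons, lats = stack.cell_center(rows, cols)
    records = [
        (f"SIM-{i:04d}", float(lon), float(lat))
        for i, (lon, lat) in enumerate(zip(lons, lats), start=1)
    ]
    return OccurrenceSet(species=species, records=records)


# -- ESRI ASCII grid I/O --------------------------------------------------

_ASC_NODATA = -9999.0


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    stack: LandscapeStack,
    nodata_mask: np.ndarray | None = None,
) -> None:
    """Write one grid as an ESRI ASCII raster (cell-center registration)."""
    n_rows, n_cols = grid.shape
    xll = stack.origin_lon
    yll = stack.origin_lat - n_rows * stack.cell_size
    out = np.asarray(grid, dtype=float).copy()
    if nodata_mask is not None:
        out[nodata_mask] = _ASC_NODATA
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {stack.cell_size!r}\n"
        f"NODATA_value {_ASC_NODATA}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in out)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path):
    """Read an ESRI ASCII raster; nodata cells become NaN.

    Returns ``(grid, header)`` where header is the geotransform tuple
    ``(n_rows, n_cols, xllcorner, yllcorner, cellsize)``.
    """
    lines = Path(path).read_text().splitlines()
    meta: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        meta[key.lower()] = float(val)
        i += 1
    grid = np.array([[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    nodata = meta.get("nodata_value", _ASC_NODATA)
    grid[grid == nodata] = np.nan
    header = (
        int(meta["nrows"]),
        int(meta["ncols"]),
        meta["xllcorner"],
        meta["yllcorner"],
        meta["cellsize"],
    )
    if grid.shape != (header[0], header[1]):
        raise ValueError(f"{path}: body shape {grid.shape} does not match header")
    return grid, header
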