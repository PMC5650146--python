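"""Discretized habitat masks with stratum labels.

A :class:`HabitatMask` is a regular grid of square cells in planar
kilometre coordinates.  Every cell is either land or water, and every
water cell carries a stratum label (``Inshore``, ``Island`` or
``Offshore``).  The mask defines the support of activity centers in the
capture-recapture model and the domain of the synthetic generator, the
kernel utilization distributions and the hot-spot grids.

Coordinates are planar kilometres in a local projection supplied by the
caller; no geodetic math is performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

LAND = "Land"
INSHORE = "Inshore"
ISLAND = "Island"
OFFSHORE = "Offshore"

#: stable integer codes used in the grid arrays
STRATUM_CODES = {LAND: 0, INSHORE: 1, ISLAND: 2, OFFSHORE: 3}
STRATUM_NAMES = {v: k for k, v in STRATUM_CODES.items()}


@dataclass(frozen=True)
class GridSpec:
    """Origin + extent + cell size of a regular grid.

    ``origin`` is the (x, y) of the lower-left corner of cell (row 0,
    col 0); rows increase with y, columns with x.
    """

    origin: tuple[float, float]
    nx: int
    ny: int
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("empty extent: nx and ny must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    def cell_centers(self) -> np.ndarray:
        """(ny*nx, 2) array of cell-center coordinates, row-major."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class HabitatMask:
    """Water/land grid with stratum labels.

    Attributes
    ----------
    origin : (x, y) of the lower-left corner, km.
    cell_size : cell edge length, km.
    water : (ny, nx) boolean grid, True where the cell is water.
    stratum : (ny, nx) int grid of stratum codes (see STRATUM_CODES).
    """

    origin: tuple[float, float]
    cell_size: float
    water: np.ndarray
    stratum: np.ndarray

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=bool)
        self.stratum = np.asarray(self.stratum, dtype=np.int8)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.water.shape != self.stratum.shape:
            raise ValueError("water and stratum grids must have equal shape")
        land = self.stratum == STRATUM_CODES[LAND]
        if not np.array_equal(land, ~self.water):
            raise ValueError("stratum must be Land exactly where water is False")

    # -- geometry -----------------------------------------------------
    @property
    def ny(self) -> int:
        return self.water.shape[0]

    @property
    def nx(self) -> int:
        return self.water.shape[1]

    @property
    def n_cells(self) -> int:
        return self.water.size

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.origin, self.nx, self.ny, self.cell_size)

    def cell_centers(self) -> np.ndarray:
        """(ny*nx, 2) centers, row-major flat order."""
        return self.grid.cell_centers()

    def water_cells(self) -> np.ndarray:
        """Flat indices of water cells."""
        return np.flatnonzero(self.water.ravel())

    def water_centers(self) -> np.ndarray:
        return self.cell_centers()[self.water_cells()]

    def stratum_flat(self) -> np.ndarray:
        return self.stratum.ravel()

    def cell_index(self, x, y) -> np.ndarray:
        """Flat cell index containing (x, y); half-open [lo, hi) cells.

        Points outside the extent return -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        r = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        ok = (c >= 0) & (c < self.nx) & (r >= 0) & (r < self.ny)
        idx = np.where(ok, r * self.nx + c, -1)
        return idx

    def is_water_xy(self, x, y) -> np.ndarray:
        idx = self.cell_index(x, y)
        out = np.zeros(np.shape(idx), dtype=bool)
        flat = self.water.ravel()
        scalar = np.ndim(idx) == 0
        idx = np.atleast_1d(idx)
        out = np.atleast_1d(out)
        ok = idx >= 0
        out[ok] = flat[idx[ok]]
        return out[0] if scalar else out

    def nearest_water_cell(self, x: float, y: float) -> int:
        """Flat index of the water cell whose center is nearest (x, y)."""
        wc = self.water_cells()
        centers = self.cell_centers()[wc]
        d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
        return int(wc[np.argmin(d2)])

    # -- queries ------------------------------------------------------
    def strata_present(self) -> list[str]:
        return [STRATUM_NAMES[c] for c in sorted(np.unique(self.stratum))]

    def stratum_cell_count(self, label: str) -> int:
        if label not in STRATUM_CODES:
            raise ValueError(f"unknown stratum label: {label!r}")
        return int(np.count_nonzero(self.stratum == STRATUM_CODES[label]))

    # -- serialization ------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rr, cc = np.meshgrid(np.arange(self.ny), np.arange(self.nx), indexing="ij")
        return pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "water": self.water.ravel().astype(int),
                "stratum": [STRATUM_NAMES[c] for c in self.stratum.ravel()],
            }
        )

    def to_csv(self, path) -> None:
        header = (
            f"# habitat mask: origin={self.origin[0]},{self.origin[1]} "
            f"cell_size={self.cell_size} nx={self.nx} ny={self.ny}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "HabitatMask":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# habitat mask:"):
                raise ValueError(f"not a habitat mask CSV: {path}")
            meta = dict(
                kv.split("=") for kv in header.split(":", 1)[1].split() if "=" in kv
            )
            df = pd.read_csv(fh)
        nx, ny = int(meta["nx"]), int(meta["ny"])
        ox, oy = (float(v) for v in meta["origin"].split(","))
        water = np.zeros((ny, nx), dtype=bool)
        stratum = np.zeros((ny, nx), dtype=np.int8)
        water[df["row"], df["col"]] = df["water"].astype(bool)
        stratum[df["row"], df["col"]] = [STRATUM_CODES[s] for s in df["stratum"]]
        return cls((ox, oy), float(meta["cell_size"]), water, stratum)

    def to_npz(self, path) -> None:
        """Compact binary cache (runtime convenience, not an exchange format)."""
        np.savez_compressed(
            path,
            origin=np.asarray(self.origin, dtype=float),
            cell_size=np.asarray([self.cell_size]),
            water=self.water,
            stratum=self.stratum,
        )

    @classmethod
    def from_npz(cls, path) -> "HabitatMask":
        with np.load(path) as z:
            return cls(
                tuple(z["origin"]), float(z["cell_size"][0]), z["water"], z["stratum"]
            )


def stratum_area(mask: HabitatMask, stratum: str) -> float:
    """Area (km^2) of a stratum on the mask: cell count x cell_size^2."""
    return mask.stratum_cell_count(stratum) * mask.cell_size**2


@dataclass(frozen=True)
class StratumAreas:
    """Configured stratum areas (km^2) used for abundance extrapolation.

    The defaults are the survey-region totals: Island 242 km^2 and
    Inshore 2,196 km^2.
    """

    area_by_stratum: dict = field(
        default_factory=lambda: {ISLAND: 242.0, INSHORE: 2196.0}
    )

    def __post_init__(self) -> None:
        for k, v in self.area_by_stratum.items():
            if v <= 0:
                raise ValueError(f"stratum area must be > 0 ({k}={v})")

    def __getitem__(self, label: str) -> float:
        if label not in self.area_by_stratum:
            raise ValueError(f"no configured area for stratum {label!r}")
        return self.area_by_stratum[label]

    @property
    def total(self) -> float:
        return float(sum(self.area_by_stratum.values()))


def build_mask(
    land_polygons: Iterable,
    island_polygons: Iterable,
    grid: GridSpec,
    *,
    pass_corridors: Iterable = (),
    island_buffer_km: float = 1.0,
    offshore_buffer_km: float = 2.0,
) -> HabitatMask:
    """Rasterize shoreline polygons into a labelled habitat mask.

    Cells whose centers fall inside any land or island polygon are Land
    (boundary points count as inside).  Water cells within
    ``island_buffer_km`` of an island polygon, or inside an explicit pass
    corridor polygon, are Island.  Water cells between the island buffer
    and ``offshore_buffer_km`` are Offshore.  All remaining water cells
    are Inshore.

    Pass corridors are explicit input polygons: the corridor geometry in
    the passes between islands is survey-specific and cannot be inferred
    from the shoreline alone.
    """
    land_polygons = list(land_polygons)
    island_polygons = list(island_polygons)
    pass_corridors = list(pass_corridors)
    for poly in land_polygons + island_polygons + pass_corridors:
        if not poly.is_valid:
            raise ValueError("invalid (self-intersecting?) polygon input")

    centers = grid.cell_centers()
    pts = shapely.points(centers[:, 0], centers[:, 1])

    all_land = land_polygons + island_polygons
    if all_land:
        land_u = unary_union(all_land)
        is_land = shapely.covers(land_u, pts)
    else:
        is_land = np.zeros(len(pts), dtype=bool)
    water = ~is_land
    if not water.any():
        raise ValueError("zero water cells in extent")

    stratum = np.full(len(pts), STRATUM_CODES[INSHORE], dtype=np.int8)
    stratum[is_land] = STRATUM_CODES[LAND]

    if island_polygons:
        island_u = unary_union(island_polygons)
        dist = shapely.distance(pts, island_u)
        in_corridor = np.zeros(len(pts), dtype=bool)
        if pass_corridors:
            corridor_u = unary_union(pass_corridors)
            in_corridor = shapely.covers(corridor_u, pts)
        is_island = water & ((dist <= island_buffer_km) | in_corridor)
        is_offshore = water & ~is_island & (dist <= offshore_buffer_km)
        stratum[is_island] = STRATUM_CODES[ISLAND]
        stratum[is_offshore] = STRATUM_CODES[OFFSHORE]

    return HabitatMask(
        grid.origin,
        grid.cell_size,
        water.reshape(grid.ny, grid.nx),
        stratum.reshape(grid.ny, grid.nx),
    )


# -- GeoJSON I/O for polygon inputs ----------------------------------

def read_polygons_geojson(path) -> list:
    """Read polygons from a GeoJSON file (FeatureCollection or geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        for feat in gj["features"]:
            geoms.append(shape(feat["geometry"]))
    elif gj.get("type") == "Feature":
        geoms.append(shape(gj["geometry"]))
    else:
        geoms.append(shape(gj))
    return geoms


def write_polygons_geojson(polygons: Sequence, path, properties=None) -> None:
    feats = []
    for i, poly in enumerate(polygons):
        props = dict(properties[i]) if properties else {}
        feats.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
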