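"""Argos filtering and kernel utilization-distribution home ranges.

Implements the LC3/LC2 + one-location-per-day filter, a
connectivity-preserving ad hoc bandwidth rule, barrier-aware Gaussian
kernel UDs (mask-and-renormalize over water), 50%/95% contour areas,
maximum range dimension, and grouped summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist

from .habitat import HabitatMask

KEEP_CLASSES = ("3", "2")
MIN_LOCATIONS = 150


@dataclass
class UDGrid:
    """Kernel utilization distribution aligned to a habitat mask.

    ``values`` is (ny, nx), sums to 1 over water cells, zero on land.
    """

    values: np.ndarray
    h: float
    mask: HabitatMask
    animal_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.water.shape:
            raise ValueError("UD grid shape must match habitat mask")
        if (self.values < 0).any():
            raise ValueError("UD values must be nonnegative")
        if self.values[~self.mask.water].any():
            raise ValueError("UD must be zero on land")
        total = self.values.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"UD must sum to 1 over water cells (got {total})")


@dataclass(frozen=True)
class RangeMetrics:
    """Per-animal home-range summary."""

    animal_id: str
    area95: float
    area50: float
    max_dimension: float
    n_locations: int

    def __post_init__(self):
        if self.area50 > self.area95 + 1e-9:
            raise ValueError("core (50%) area cannot exceed home (95%) area")
        if self.max_dimension < 0:
            raise ValueError("max_dimension must be >= 0")


def filter_locations(
    raw: pd.DataFrame,
    seed: int,
    *,
    keep_classes: tuple = KEEP_CLASSES,
    min_locations: int = MIN_LOCATIONS,
) -> pd.DataFrame:
    """Keep LC3/LC2 fixes, then one random fix per animal-day.

    Deterministic given ``seed``.  Animals whose filtered fix count
    falls below ``min_locations`` are flagged in ``df.attrs["below_threshold"]``
    (they still receive range calculations downstream).
    """
    required = {"animal_id", "timestamp", "lc", "x_km", "y_km"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"telemetry table missing columns: {sorted(missing)}")
    df = raw.copy()
    df["lc"] = df["lc"].astype(str)
    df = df[df["lc"].isin([str(c) for c in keep_classes])]
    if len(df) == 0:
        out = df.reset_index(drop=True)
        out.attrs["below_threshold"] = []
        return out
    ts = pd.to_datetime(df["timestamp"])
    df = df.assign(_day=ts.dt.date)
    rng = np.random.default_rng(seed)
    # stable order first so the random choice is reproducible
    df = df.sort_values(["animal_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    picks = df.groupby(["animal_id", "_day"], sort=True).indices
    chosen = [int(rng.choice(idx)) for _, idx in sorted(picks.items(), key=lambda kv: kv[0])]
    out = df.loc[sorted(chosen)].drop(columns="_day").reset_index(drop=True)
    counts = out["animal_id"].value_counts()
    below = sorted(counts[counts < min_locations].index)
    if below:
        warnings.warn(
            f"{len(below)} animal(s) below the {min_locations}-location threshold: {below}"
        )
    out.attrs["below_threshold"] = below
    return out


def reference_bandwidth(points: np.ndarray) -> float:
    """Bivariate-normal reference bandwidth h_ref = s * n^(-1/6)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    s = np.sqrt(0.5 * (points[:, 0].var(ddof=1) + points[:, 1].var(ddof=1)))
    return float(s * n ** (-1.0 / 6.0))


def kernel_ud(
    points: np.ndarray, h: float, mask: HabitatMask, animal_id: str | None = None
) -> UDGrid:
    """Gaussian kernel density on the mask grid, land masked out and the
    remaining mass renormalized to one."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    centers = mask.cell_centers()
    d2 = (
        (centers[:, None, 0] - points[None, :, 0]) ** 2
        + (centers[:, None, 1] - points[None, :, 1]) ** 2
    )
    dens = np.exp(-d2 / (2.0 * h * h)).sum(axis=1)
    dens[~mask.water.ravel()] = 0.0
    total = dens.sum()
    if total <= 0:
        raise ValueError("zero total UD mass after land masking")
    return UDGrid(
        (dens / total).reshape(mask.ny, mask.nx), float(h), mask, animal_id
    )


def contour_cells(ud: UDGrid, level: float) -> np.ndarray:
    """Boolean grid of the minimal highest-density cell set holding
    cumulative mass >= level."""
    flat = ud.values.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, (flat > 0).sum())
    sel = np.zeros(flat.size, dtype=bool)
    sel[order[:k]] = True
    return sel.reshape(ud.values.shape)


def ud_contour_area(ud: UDGrid, level: float) -> float:
    """Area (km^2) of the ``level`` contour; disconnected regions allowed."""
    cells = contour_cells(ud, level)
    return float(cells.sum()) * ud.mask.cell_size**2


def select_bandwidth(
    points: np.ndarray,
    mask: HabitatMask,
    *,
    multipliers: np.ndarray | None = None,
    level: float = 0.95,
    min_points: int = 5,
) -> float:
    """Rule-based ad hoc bandwidth: shrink the reference bandwidth while
    the 95% UD stays a single connected region holding >= 95% of points.

    Candidates ``multipliers * h_ref`` are evaluated in descending order;
    the smallest satisfying bandwidth is returned, or ``h_ref`` when no
    candidate (including 1.0) satisfies the rule.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < min_points:
        raise ValueError(f"need at least {min_points} points to select a bandwidth")
    h_ref = reference_bandwidth(points)
    if h_ref <= 0 or not np.isfinite(h_ref):
        raise ValueError("degenerate point cloud: zero-variance bandwidth")
    if multipliers is None:
        multipliers = np.round(np.arange(1.0, 0.05, -0.1), 10)
    best = None
    for m in sorted(multipliers, reverse=True):
        h = m * h_ref
        try:
            ud = kernel_ud(points, h, mask)
        except ValueError:
            break
        cells = contour_cells(ud, level)
        _, n_regions = ndimage.label(cells, structure=np.ones((3, 3)))
        idx = mask.cell_index(points[:, 0], points[:, 1])
        inside = cells.ravel()[np.clip(idx, 0, None)] & (idx >= 0)
        if n_regions == 1 and inside.mean() >= level:
            best = h
        else:
            break
    return float(best) if best is not None else float(h_ref)


def max_distance(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance between locations (km)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise ValueError("no points")
    if len(points) == 1:
        return 0.0
    return float(pdist(points).max())


def compute_range_metrics(
    animal_id: str,
    points: np.ndarray,
    mask: HabitatMask,
    *,
    h: float | None = None,
) -> RangeMetrics:
    """95%/50% UD areas and maximum dimension for one animal."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if h is None:
        h = select_bandwidth(points, mask)
    ud = kernel_ud(points, h, mask, animal_id)
    return RangeMetrics(
        animal_id=animal_id,
        area95=ud_contour_area(ud, 0.95),
        area50=ud_contour_area(ud, 0.50),
        max_dimension=max_distance(points),
        n_locations=len(points),
    )


def metrics_frame(metrics: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": m.animal_id,
                "area95_km2": m.area95,
                "area50_km2": m.area50,
                "max_dimension_km": m.max_dimension,
                "n_locations": m.n_locations,
            }
            for m in metrics
        ]
    )


def range_summary(frame: pd.DataFrame, by: list) -> pd.DataFrame:
    """Arithmetic mean and sample SD of each numeric column per group.

    Single-animal groups report SD as NaN.
    """
    if len(frame) == 0:
        raise ValueError("no range metrics to summarize")
    num_cols = [c for c in frame.columns if c not in by and pd.api.types.is_numeric_dtype(frame[c])]
    g = frame.groupby(by, sort=True)
    mean = g[num_cols].mean()
    sd = g[num_cols].std(ddof=1)
    n = g.size().rename("n")
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").join(n).reset_index()
    return out


def ud_to_csv(ud: UDGrid, path) -> None:
    df = pd.DataFrame(
        {
            "row": np.repeat(np.arange(ud.mask.ny), ud.mask.nx),
            "col": np.tile(np.arange(ud.mask.nx), ud.mask.ny),
            "density": ud.values.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# ud: animal={ud.animal_id} h={ud.h}\n")
        df.to_csv(fh, index=False)


def contours_to_geojson(ud: UDGrid, levels, path) -> None:
    """Export contour cell sets as GeoJSON cell polygons."""
    import json

    feats = []
    x0, y0 = ud.mask.origin
    cs = ud.mask.cell_size
    for level in levels:
        cells = contour_cells(ud, level)
        for r, c in zip(*np.nonzero(cells)):
            xa, ya = x0 + c * cs, y0 + r * cs
            ring = [
                [xa, ya], [xa + cs, ya], [xa + cs, ya + cs], [xa, ya + cs], [xa, ya]
            ]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"level": level, "animal_id": ud.animal_id},
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
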