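"""Monthly gridding, Getis-Ord Gi* hot spots and month-to-month overlap.

Fix counts are summed on a 1 km^2 grid per month; the Gi* distance
threshold is chosen by scanning Global Moran's I z-scores across
distance bands (first local maximum); each cell's local sum includes
itself and at least eight neighbours; hot cells are positive-Z cells
significant at alpha with no multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .habitat import GridSpec


@dataclass
class CountGrid:
    """Monthly fix counts on a regular grid."""

    month: str
    counts: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("counts shape must match grid spec")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GiGrid:
    """Per-cell Gi* z-scores and p-values."""

    month: str
    z: np.ndarray
    p: np.ndarray
    grid: GridSpec
    threshold_km: float
    min_neighbors: int = 8


@dataclass(frozen=True)
class HotspotSet:
    """Significant hot cells (Z > 0, p < alpha) for one month."""

    month: str
    alpha: float
    cells: frozenset
    grid: GridSpec = field(compare=False, default=None)

    def __len__(self) -> int:
        return len(self.cells)


def grid_counts(fixes: pd.DataFrame, month: str, grid: GridSpec) -> CountGrid:
    """Sum fixes for ``month`` (\"YYYY-MM\") onto the grid.

    Cell assignment uses the half-open convention [x, x+cs) x [y, y+cs).
    Fixes outside the extent raise, listing the offending rows.
    """
    ts = pd.to_datetime(fixes["timestamp"])
    sel = ts.dt.strftime("%Y-%m") == month
    sub = fixes[sel]
    counts = np.zeros((grid.ny, grid.nx), dtype=int)
    if len(sub) == 0:
        warnings.warn(f"no fixes in month {month}; empty grid")
        return CountGrid(month, counts, grid)
    c = np.floor((sub["x_km"].to_numpy() - grid.origin[0]) / grid.cell_size).astype(int)
    r = np.floor((sub["y_km"].to_numpy() - grid.origin[1]) / grid.cell_size).astype(int)
    bad = (c < 0) | (c >= grid.nx) | (r < 0) | (r >= grid.ny)
    if bad.any():
        offenders = sub.index[bad].tolist()
        raise ValueError(f"fixes outside grid extent at rows {offenders[:20]}")
    np.add.at(counts, (r, c), 1)
    return CountGrid(month, counts, grid)


def _cell_coords(grid: GridSpec) -> np.ndarray:
    return grid.cell_centers()


def _pairwise_dist(grid: GridSpec) -> np.ndarray:
    return squareform(pdist(_cell_coords(grid)))


def morans_i(grid: CountGrid, threshold: float) -> tuple[float, float]:
    """Global Moran's I with binary distance-band weights (self excluded)
    and its z-score under the normality assumption."""
    x = grid.counts.ravel().astype(float)
    n = x.size
    if x.var() == 0:
        raise ValueError("zero variance: Moran's I undefined on a constant field")
    D = _pairwise_dist(grid.grid)
    W = ((D <= threshold) & (D > 0)).astype(float)
    s0 = W.sum()
    if s0 == 0:
        raise ValueError(f"no neighbour pairs within threshold {threshold}")
    z = x - x.mean()
    num = float(z @ W @ z)
    den = float((z**2).sum())
    I = (n / s0) * num / den

    # moments under normality
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    zscore = (I - e_i) / np.sqrt(var_i)
    return float(I), float(zscore)


def average_nearest_neighbor(grid: CountGrid) -> float:
    """Mean distance from each nonzero cell center to its nearest
    nonzero neighbour."""
    coords = _cell_coords(grid.grid)[grid.counts.ravel() > 0]
    if len(coords) < 2:
        raise ValueError("need >= 2 nonzero cells for nearest-neighbor distance")
    D = squareform(pdist(coords))
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


def isa_threshold(
    grid: CountGrid,
    start: float | None = None,
    step: float | None = None,
    n_steps: int = 10,
) -> float:
    """Distance at which spatial autocorrelation first peaks.

    Runs Moran's I at ``start, start + step, ...`` and returns the first
    local maximum of the z-score sequence; if the z-score is still
    rising at the last tested distance, that distance is returned with a
    warning.  ``start`` and ``step`` default to the average
    nearest-neighbor distance of the nonzero cells.
    """
    if grid.counts.ravel().var() == 0:
        raise ValueError("zero variance: cannot scan spatial autocorrelation")
    ann = average_nearest_neighbor(grid)
    start = ann if start is None else start
    step = ann if step is None else step
    dists, zs = [], []
    for i in range(n_steps):
        d = start + i * step
        try:
            _, zscore = morans_i(grid, d)
        except ValueError:
            continue
        dists.append(d)
        zs.append(zscore)
    if not zs:
        raise ValueError("no usable distance bands in scan")
    for i in range(1, len(zs) - 1):
        if zs[i] > zs[i - 1] and zs[i] >= zs[i + 1]:
            return dists[i]
    if len(zs) >= 2 and zs[0] > zs[1]:
        return dists[0]
    warnings.warn("Moran's I z-score monotone over scan; returning last distance")
    return dists[-1]


def getis_ord_gi_star(
    grid: CountGrid, threshold: float, min_neighbors: int = 8
) -> GiGrid:
    """Gi* z-score per cell with binary weights, self included.

    Neighbours are all cells within ``threshold``; any cell with fewer
    than ``min_neighbors`` others in range has its threshold extended to
    its ``min_neighbors`` nearest cells.  p-values are two-sided normal.
    """
    x = grid.counts.ravel().astype(float)
    n = x.size
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0:
        raise ValueError("zero variance: Gi* undefined on a constant field")
    D = _pairwise_dist(grid.grid)
    z = np.empty(n)
    for i in range(n):
        d = D[i]
        thr = threshold
        others = np.sort(d[np.arange(n) != i])
        if len(others) >= min_neighbors and others[min_neighbors - 1] > thr:
            thr = others[min_neighbors - 1]
        w = (d <= thr).astype(float)  # includes self (d=0)
        sw = w.sum()
        sw2 = (w**2).sum()
        num = float(w @ x) - xbar * sw
        den = s * np.sqrt((n * sw2 - sw**2) / (n - 1))
        z[i] = num / den
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return GiGrid(
        grid.month,
        z.reshape(grid.counts.shape),
        p.reshape(grid.counts.shape),
        grid.grid,
        float(threshold),
        min_neighbors,
    )


def classify_hotspots(gi: GiGrid, alpha: float) -> HotspotSet:
    """Cells with Z > 0 and p < alpha (no multiple-testing correction)."""
    hot = (gi.z > 0) & (gi.p < alpha)
    cells = frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(hot)))
    return HotspotSet(gi.month, alpha, cells, gi.grid)


def hotspot_overlap(a: HotspotSet, b: HotspotSet) -> tuple[int, float]:
    """Shared-cell count and overlap percentage between two months.

    Percent = 100 * |a ∩ b| / |a ∪ b| — the shared count divided by the
    total hot spots of the two comparison months.
    """
    if a.alpha != b.alpha:
        raise ValueError("hot spot sets must use the same alpha")
    inter = a.cells & b.cells
    union = a.cells | b.cells
    if not union:
        warnings.warn("both hot spot sets empty; overlap percentage undefined")
        return 0, float("nan")
    return len(inter), 100.0 * len(inter) / len(union)


def gi_to_frame(gi: GiGrid, alpha_pairs=(0.05, 0.01)) -> pd.DataFrame:
    ny, nx = gi.z.shape
    df = pd.DataFrame(
        {
            "row": np.repeat(np.arange(ny), nx),
            "col": np.tile(np.arange(nx), ny),
            "z": gi.z.ravel(),
            "p": gi.p.ravel(),
        }
    )
    for a in alpha_pairs:
        df[f"hot{str(a).split('.')[1]}"] = ((gi.z.ravel() > 0) & (gi.p.ravel() < a)).astype(int)
    return df


def hotspots_to_geojson(hs: HotspotSet, path) -> None:
    import json

    grid = hs.grid
    x0, y0 = grid.origin
    cs = grid.cell_size
    feats = []
    for r, c in sorted(hs.cells):
        xa, ya = x0 + c * cs, y0 + r * cs
        ring = [[xa, ya], [xa + cs, ya], [xa + cs, ya + cs], [xa, ya + cs], [xa, ya]]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"month": hs.month, "alpha": hs.alpha},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
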