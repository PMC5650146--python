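"""Capture histories and descriptive photo-ID statistics.

Turns sighting tables into per-individual capture histories and
computes marked proportions, discovery curves, site-fidelity bins,
sighting-frequency counts and group-size summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKED_CLASSES = ("D1", "D2")
LSF, MSF, HSF = "LSF", "MSF", "HSF"


@dataclass
class CaptureHistorySet:
    """Binary detection arrays per marked individual.

    ``matrix`` has shape (n_individuals, n_primaries, n_secondaries);
    ``mean_locations`` has shape (n_individuals, n_primaries, 2) with
    NaN where an individual was not detected in a primary.
    """

    ids: list
    matrix: np.ndarray
    mean_locations: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 3:
            raise ValueError("matrix must be (individuals, primaries, secondaries)")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids and matrix disagree on individual count")
        if self.matrix.size and not self.matrix.reshape(len(self.ids), -1).any(axis=1).all():
            raise ValueError("every individual must have at least one detection")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_primaries(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_secondaries(self) -> int:
        return self.matrix.shape[2]

    def primaries_seen(self) -> np.ndarray:
        """Per individual, number of primaries with >= 1 detection."""
        return (self.matrix.max(axis=2) > 0).sum(axis=1)

    def first_primary(self) -> np.ndarray:
        """Per individual, 0-based index of first primary detected."""
        seen = self.matrix.max(axis=2) > 0
        return seen.argmax(axis=1)

    def to_wide_frame(self) -> pd.DataFrame:
        cols = [
            f"p{t + 1}s{k + 1}"
            for t in range(self.n_primaries)
            for k in range(self.n_secondaries)
        ]
        return pd.DataFrame(
            self.matrix.reshape(self.n_individuals, -1), index=self.ids, columns=cols
        ).rename_axis("id")

    def to_long_frame(self) -> pd.DataFrame:
        idx, tt, kk = np.nonzero(self.matrix)
        return pd.DataFrame(
            {
                "id": [self.ids[i] for i in idx],
                "primary": tt + 1,
                "secondary": kk + 1,
            }
        )


@dataclass(frozen=True)
class MarkedProportion:
    """Marked / photographed tally for one primary period."""

    primary: int
    marked: int
    photographed: int

    @property
    def proportion(self) -> float:
        return self.marked / self.photographed

    @property
    def se(self) -> float:
        p = self.proportion
        return math.sqrt(p * (1.0 - p) / self.photographed)

    @property
    def inflation(self) -> float:
        """Density inflation factor 1/p applied to marked-scale density."""
        if self.proportion == 0:
            raise ValueError("zero marked proportion: inflation undefined")
        return 1.0 / self.proportion


def _validate_sightings(sightings: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "primary", "secondary", "distinctiveness"}
    missing = required - set(sightings.columns)
    if missing:
        raise ValueError(f"sighting table missing columns: {sorted(missing)}")
    df = sightings.copy()
    df["id"] = df["id"].fillna("").astype(str)
    marked = df["distinctiveness"].isin(MARKED_CLASSES)
    if (marked & (df["id"] == "")).any():
        raise ValueError("marked rows (D1/D2) must carry a non-blank id")
    return df


def build_capture_histories(
    sightings: pd.DataFrame,
    n_primaries: int | None = None,
    n_secondaries: int | None = None,
) -> CaptureHistorySet:
    """One binary history per distinct marked individual.

    Cell (t, k) is 1 iff the individual has >= 1 record in primary t,
    secondary k; duplicate rows collapse.  Unmarked rows are excluded.
    """
    df = _validate_sightings(sightings)
    df = df[df["distinctiveness"].isin(MARKED_CLASSES)]
    P = int(n_primaries if n_primaries is not None else (df["primary"].max() if len(df) else 0))
    K = int(n_secondaries if n_secondaries is not None else (df["secondary"].max() if len(df) else 0))
    if len(df):
        bad = (
            (df["primary"] < 1) | (df["primary"] > P)
            | (df["secondary"] < 1) | (df["secondary"] > K)
        )
        if bad.any():
            raise ValueError(
                f"malformed primary/secondary indices outside design {P}x{K}"
            )
    ids = sorted(df["id"].unique())
    pos = {i: j for j, i in enumerate(ids)}
    matrix = np.zeros((len(ids), P, K), dtype=np.uint8)
    if len(df):
        matrix[
            df["id"].map(pos).to_numpy(),
            df["primary"].to_numpy() - 1,
            df["secondary"].to_numpy() - 1,
        ] = 1
    mean_loc = np.full((len(ids), P, 2), np.nan)
    if len(df) and {"x_km", "y_km"}.issubset(df.columns):
        g = df.groupby(["id", "primary"])[["x_km", "y_km"]].mean()
        for (ind, t), row in g.iterrows():
            mean_loc[pos[ind], int(t) - 1] = row.to_numpy()
    return CaptureHistorySet(ids, matrix, mean_loc)


def marked_proportion(
    sightings: pd.DataFrame, primary: int, *, exclude_calves: bool = True
) -> MarkedProportion:
    """Marked proportion for one primary, counting photographed rows.

    The denominator is every photographed dolphin (marked + unmarked);
    rows flagged in a boolean ``calf`` column are excluded by default.
    """
    df = _validate_sightings(sightings)
    df = df[df["primary"] == primary]
    if exclude_calves and "calf" in df.columns:
        df = df[~df["calf"].astype(bool)]
    photographed = len(df)
    if photographed == 0:
        raise ValueError(f"no photographed dolphins in primary {primary}")
    marked = int(df["distinctiveness"].isin(MARKED_CLASSES).sum())
    return MarkedProportion(primary, marked, photographed)


def marked_proportion_from_counts(marked: int, photographed: int, primary: int = 0) -> MarkedProportion:
    """MarkedProportion from externally tallied counts."""
    if photographed <= 0:
        raise ValueError("photographed count must be > 0")
    if marked > photographed:
        raise ValueError("marked count cannot exceed photographed count")
    return MarkedProportion(primary, marked, photographed)


def discovery_curve(histories: CaptureHistorySet) -> np.ndarray:
    """Cumulative count of new marked individuals per primary."""
    if histories.n_primaries < 1:
        raise ValueError("need at least one primary period")
    first = histories.first_primary()
    new_per = np.bincount(first, minlength=histories.n_primaries)
    return np.cumsum(new_per)


def site_fidelity_bins(
    histories: CaptureHistorySet, edges: tuple = (2, 4)
) -> pd.Series:
    """Per-individual site-fidelity bin.

    Individuals seen in <= edges[0] primaries are LSF, <= edges[1] MSF,
    and more than edges[1] HSF (defaults 1-2 / 3-4 / >=5 for the
    8-primary design).
    """
    seen = histories.primaries_seen()
    if (seen == 0).any():
        raise ValueError("individual with zero detections violates history invariant")
    bins = np.where(seen <= edges[0], LSF, np.where(seen <= edges[1], MSF, HSF))
    return pd.Series(bins, index=pd.Index(histories.ids, name="id"), name="site_fidelity")


def sighting_frequency(histories: CaptureHistorySet) -> pd.Series:
    """Number of individuals by count of primaries in which they were seen."""
    seen = histories.primaries_seen()
    counts = pd.Series(seen).value_counts().sort_index()
    counts.index.name = "n_primaries_seen"
    return counts.rename("n_individuals")


def percent_sighted_once(n_once: int, n_total: int) -> float:
    """Percentage of the catalog sighted in exactly one primary."""
    if n_total <= 0:
        raise ValueError("catalog size must be > 0")
    return 100.0 * n_once / n_total


def summarize_sightings(sightings: pd.DataFrame, season_map: dict) -> pd.DataFrame:
    """Group-size mean/SE per season.

    ``season_map`` maps primary index -> season label.  Group sizes are
    taken once per distinct (primary, group_id).  SE = SD / sqrt(n); a
    single-group season reports SE as NaN.  Seasons with no groups are
    omitted with a warning.
    """
    df = _validate_sightings(sightings)
    missing = set(df["primary"].unique()) - set(season_map)
    if missing:
        raise ValueError(f"primaries without season assignment: {sorted(missing)}")
    groups = (
        df.drop_duplicates(["primary", "group_id"])[["primary", "group_id", "group_size"]]
        .assign(season=lambda d: d["primary"].map(season_map))
    )
    out = []
    for season in dict.fromkeys(season_map.values()):
        sizes = groups.loc[groups["season"] == season, "group_size"].to_numpy(float)
        if len(sizes) == 0:
            warnings.warn(f"season {season!r} has no groups; omitted")
            continue
        mean = sizes.mean()
        se = sizes.std(ddof=1) / math.sqrt(len(sizes)) if len(sizes) > 1 else np.nan
        out.append({"season": season, "n_groups": len(sizes), "mean_group_size": mean, "se": se})
    return pd.DataFrame(out, columns=["season", "n_groups", "mean_group_size", "se"])
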