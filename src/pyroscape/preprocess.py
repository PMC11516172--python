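"""Occurrence thinning, covariate screening, landscape diversity, cross-tabs.

These are the data-preparation steps run before any model fit: distance
thinning of occurrence points to damp spatial autocorrelation (1 km for
species records, 300 m for satellite fire detections, matching the sensor
footprint), pairwise-correlation screening of covariates (|r| cutoffs 0.85
for habitat models, 0.75 for fire models), a moving-window Shannon
diversity of the land-use map, and land-use cross-tabulation of fire
points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import GridValidationError, OccurrenceSet, RasterGrid


@dataclass
class CrossTabTable:
    """Per-class frequency and percentage of occurrence points.

    Percentages are 100 * frequency / total, reported to 2 decimals; the
    denominator is the table's own frequency total (per-season totals when
    built per season).
    """

    table: pd.DataFrame  # columns: class_name, frequency, percentage

    @classmethod
    def from_frequencies(cls, freqs: dict[str, int] | pd.Series) -> "CrossTabTable":
        s = pd.Series(freqs, dtype=int)
        total = int(s.sum())
        if total == 0:
            raise GridValidationError("cross-tab needs at least one point")
        pct = (100.0 * s / total).round(2)
        return cls(pd.DataFrame({
            "class_name": s.index, "frequency": s.to_numpy(),
            "percentage": pct.to_numpy()}).reset_index(drop=True))

    def percentage_of(self, class_name: str) -> float:
        row = self.table[self.table["class_name"] == class_name]
        if row.empty:
            raise KeyError(class_name)
        return float(row["percentage"].iloc[0])


@dataclass
class ScreeningReport:
    """Outcome of iterative pairwise-correlation screening."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped layer, partner, |r|)
    threshold: float
    flagged_constant: list[str]


def thin_points(points: OccurrenceSet, min_distance: float,
                per_season: bool = True, shuffle_seed: int | None = None) -> OccurrenceSet:
    """Greedy distance thinning: keep a point iff it is at least
    ``min_distance`` from every already-kept point, scanning in input order.

    Thinning is applied within each season by default (records from
    different seasons do not exclude each other).  ``shuffle_seed``
    permutes the scan order first, for sensitivity checks.
    """
    if min_distance < 0:
        raise GridValidationError("min_distance must be >= 0")
    if len(points) == 0 or min_distance == 0:
        return points
    if per_season:
        parts = []
        for season in points.table["season"].unique():
            parts.append(
                thin_points(points.season(season), min_distance,
                            per_season=False, shuffle_seed=shuffle_seed).table)
        return OccurrenceSet(pd.concat(parts, ignore_index=True))
    table = points.table
    if shuffle_seed is not None:
        table = table.sample(frac=1.0, random_state=shuffle_seed).reset_index(drop=True)
    xy = table[["x", "y"]].to_numpy(float)
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    for i in range(len(xy)):
        if kept_xy.shape[0] == 0 or np.min(
                np.hypot(kept_xy[:, 0] - xy[i, 0], kept_xy[:, 1] - xy[i, 1])
        ) >= min_distance:
            kept.append(i)
            kept_xy = np.vstack([kept_xy, xy[i]])
    return OccurrenceSet(table.iloc[kept])


def correlation_screen(features: pd.DataFrame, threshold: float) -> ScreeningReport:
    """Iteratively remove covariates until no pair exceeds |r| > threshold.

    At each step the most-offending pair (largest |r|) loses the member
    with the larger mean |r| against all remaining layers (ties drop the
    later column).  Constant columns have undefined correlations: they are
    kept and flagged.  Pearson r is computed on complete rows.
    """
    if not 0 < threshold <= 1:
        raise GridValidationError("threshold must be in (0, 1]")
    if features.shape[1] < 2 or features.shape[0] < 3:
        raise GridValidationError("screening needs >= 2 columns and >= 3 rows")
    complete = features.dropna()
    constant = [c for c in complete.columns if complete[c].nunique() <= 1]
    active = [c for c in features.columns if c not in constant]
    dropped: list[tuple[str, str, float]] = []
    while len(active) >= 2:
        corr = complete[active].corr(method="pearson").abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = float(corr.values.max())
        if max_r <= threshold:
            break
        i, j = np.unravel_index(int(corr.values.argmax()), corr.shape)
        a, b = corr.columns[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b:
            loser, partner = a, b
        elif mean_b > mean_a:
            loser, partner = b, a
        else:  # tie: drop the later-named (later column order)
            ia, ib = active.index(a), active.index(b)
            loser, partner = (b, a) if ib > ia else (a, b)
        dropped.append((loser, partner, max_r))
        active.remove(loser)
    kept = [c for c in features.columns if c in active or c in constant]
    return ScreeningReport(kept=kept, dropped=dropped, threshold=threshold,
                           flagged_constant=constant)


def window_diversity(landuse: RasterGrid, window: int = 5) -> RasterGrid:
    """Shannon diversity H = -sum p_k ln p_k of land-use classes in a
    centered moving window (edge windows truncated, nodata excluded).

    Natural log; H ranges over [0, ln k] and is 0 where the window is
    mono-class.  Cells whose whole window is nodata come out nodata.
    """
    if window < 3 or window % 2 == 0:
        raise GridValidationError("window must be an odd integer >= 3")
    values = landuse.values
    valid = landuse.valid
    classes = np.unique(values[valid]) if valid.any() else np.array([], dtype=values.dtype)
    kernel = np.ones((window, window))
    total = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    h = np.zeros(landuse.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in classes:
            count = ndimage.convolve(((values == k) & valid).astype(float),
                                     kernel, mode="constant", cval=0.0)
            p = np.where(total > 0, count / np.maximum(total, 1e-300), 0.0)
            h -= np.where(p > 0, p * np.log(p), 0.0)
    # convolution of indicator fields is float; clamp tiny negative noise
    h = np.clip(h, 0.0, None)
    out_mask = total < 0.5
    h[out_mask] = np.nan
    return landuse.like(h, nodata_mask=out_mask)


def crosstab_landuse(points: OccurrenceSet, landuse: RasterGrid) -> CrossTabTable:
    """Count occurrence points per land-use class; report percentages.

    Classes with zero points are omitted.  Points landing on nodata cells
    are tallied in an explicit ``unclassified`` row; points outside the
    extent are rejected.
    """
    if len(points) == 0:
        raise GridValidationError("cross-tab needs at least one point")
    xy = points.xy()
    row, col = landuse.cell_of(xy[:, 0], xy[:, 1])
    nrow, ncol = landuse.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    if not inside.all():
        raise GridValidationError(
            f"{int((~inside).sum())} point(s) fall outside the land-use extent")
    legend = landuse.legend or {}
    counts: dict[str, int] = {}
    codes = landuse.values[row, col]
    on_nodata = landuse.nodata_mask[row, col]
    for code, nd in zip(codes, on_nodata):
        name = "unclassified" if nd else legend.get(int(code), str(int(code)))
        counts[name] = counts.get(name, 0) + 1
    return CrossTabTable.from_frequencies(counts)
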