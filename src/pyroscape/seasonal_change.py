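"""Normalized between-season change surface.

For risk maps ``a`` (earlier season) and ``b`` (later season) the change
index is |b - a| / max|b - a|, the max taken over cells valid in both
maps.  The index lies in [0, 1] and attains 1 somewhere unless the maps
are identical, in which case it is identically 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import GridValidationError, RasterGrid


@dataclass
class SeasonalChangeMap:
    a: RasterGrid
    b: RasterGrid
    index: RasterGrid
    season_pair: str = ""


def change_index(a: RasterGrid, b: RasterGrid, season_pair: str = "") -> SeasonalChangeMap:
    """Normalized absolute risk change between two seasons.

    Symmetric in (a, b) and invariant to scaling the difference field by
    any positive constant.
    """
    if not a.aligned_with(b):
        raise GridValidationError("season maps are not aligned")
    valid = a.valid & b.valid
    diff = np.where(valid, np.abs(b.values - a.values), 0.0)
    peak = diff[valid].max() if valid.any() else 0.0
    index = diff / peak if peak > 0 else np.zeros_like(diff)
    return SeasonalChangeMap(a, b, a.like(index, nodata_mask=~valid), season_pair)
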