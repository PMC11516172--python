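"""GAP overlap of binary habitat and binary fire-risk maps.

Overlaying the two binary maps partitions the valid landscape into four
classes — habitat at risk of fire (habitat AND fire), fire-only,
habitat-only, and neither — with areas accounted in km² from the metric
cell size.  The class raster uses codes 1–4 with a legend mirroring the
conventional red (at-risk habitat) / blue (fire only) / green (habitat
only) map semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import GridValidationError, RasterGrid

CLASS_CODES = {1: "at_risk_habitat", 2: "fire_only", 3: "habitat_only", 4: "neither"}


@dataclass
class OverlapSummary:
    """km² areas of the four-class habitat x fire partition."""

    at_risk_habitat: float
    fire_only: float
    habitat_only: float
    neither: float
    excluded_nodata: float
    species: str = ""
    season: str = ""

    @property
    def total_valid(self) -> float:
        return self.at_risk_habitat + self.fire_only + self.habitat_only + self.neither

    def as_dict(self) -> dict:
        return {
            "species": self.species, "season": self.season,
            "at_risk_habitat_km2": self.at_risk_habitat,
            "fire_only_km2": self.fire_only,
            "habitat_only_km2": self.habitat_only,
            "neither_km2": self.neither,
            "excluded_nodata_km2": self.excluded_nodata,
        }


def _check_binary(grid: RasterGrid, name: str) -> None:
    vals = grid.values[grid.valid]
    if not np.isin(vals, (0, 1)).all():
        raise GridValidationError(f"{name} map is not binary (values outside {{0, 1}})")


def gap_overlap(habitat: RasterGrid, fire: RasterGrid, species: str = "",
                season: str = "") -> tuple[RasterGrid, OverlapSummary]:
    """Partition the landscape by habitat x fire and account areas in km².

    Cells nodata in either input are excluded from all four classes and
    reported separately, so the four areas always sum to the valid area.
    """
    if not habitat.aligned_with(fire):
        raise GridValidationError("habitat and fire maps are not aligned")
    _check_binary(habitat, "habitat")
    _check_binary(fire, "fire")
    valid = habitat.valid & fire.valid
    h = habitat.values.astype(bool)
    f = fire.values.astype(bool)
    classes = np.zeros(habitat.shape, dtype=np.int8)
    classes[valid & h & f] = 1
    classes[valid & ~h & f] = 2
    classes[valid & h & ~f] = 3
    classes[valid & ~h & ~f] = 4
    area = habitat.cell_area_km2()
    summary = OverlapSummary(
        at_risk_habitat=float((classes == 1).sum()) * area,
        fire_only=float((classes == 2).sum()) * area,
        habitat_only=float((classes == 3).sum()) * area,
        neither=float((classes == 4).sum()) * area,
        excluded_nodata=float((~valid).sum()) * area,
        species=species, season=season)
    class_grid = habitat.like(classes, nodata_mask=~valid, legend=dict(CLASS_CODES))
    return class_grid, summary
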