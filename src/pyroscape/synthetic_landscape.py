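"""Synthetic seasonal landscapes with known ground truth.

Real inputs for this kind of analysis — satellite active-fire detections,
land-surface temperature (LST) and vegetation-index (NDVI) composites, a
DEM, road networks, a land-use map — are large and proprietary-ish to
acquire.  This module generates a statistical stand-in: spatially
autocorrelated continuous covariates on a common grid, a categorical
land-use layer with agricultural classes concentrated at low elevation, a
distance-to-road layer from a generated polyline, and seasonal fire-risk /
habitat-suitability surfaces defined by a known logistic model on the
standardized covariates.  Because the generating coefficients are known,
parameter- and region-recovery by the modelling pipeline can be tested.

Covariate value ranges are rescaled to magnitudes typical of a mid-latitude
mountainous study region (elevation 113–3317 m, LST 284–335 K across
seasons, NDVI −0.17–0.84) so that downstream screening and standardization
operate on realistic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grid_io import GridValidationError, OccurrenceSet, RasterGrid, RasterStack, SEASONS
from .preprocess import window_diversity

#: Seasonal additive shifts (K) applied to the temperature-like layer,
#: echoing observed seasonal LST ranges (spring ~290–323, summer ~306–334,
#: autumn ~285–314 K): summer hotter, autumn cooler than spring.
DEFAULT_SEASON_EFFECTS: dict[str, dict[str, float]] = {
    "spring": {"lst": 0.0, "ndvi": 0.0},
    "summer": {"lst": 16.0, "ndvi": -0.10},
    "autumn": {"lst": -5.0, "ndvi": -0.15},
}

#: Fire-risk coefficients on standardized layers.  Satellite-detected fire
#: occurrence is close to deterministic in the covariates — fires hug
#: roads and warm, vegetated agricultural lowlands and are essentially
#: absent elsewhere — so the generating logistic is strongly saturated:
#: the high-risk region covers only a few percent of the landscape and
#: risk is near zero outside it.  Road proximity carries the largest
#: weight, then temperature and elevation, echoing the importance ranking
#: such studies report.
DEFAULT_RISK_COEFFICIENTS: dict[str, float] = {
    "intercept": -17.0,
    "elevation": -4.0,
    "dist_road": -6.0,
    "lst": 5.0,
    "ndvi": 3.0,
    "diversity": -1.5,
    "hli": 1.5,
}

#: Two synthetic focal species: a highland ungulate avoiding roads and an
#: opportunist carnivore tied to low, human-modified terrain.  Habitat
#: selection is strong but less deterministic than fire occurrence.
DEFAULT_SPECIES_COEFFICIENTS: dict[str, dict[str, float]] = {
    "highland_ungulate": {
        "intercept": -6.0, "elevation": 3.5, "dist_road": 2.0, "ndvi": 1.0, "hli": -0.5,
    },
    "lowland_carnivore": {
        "intercept": -5.0, "elevation": -2.5, "dist_road": -1.5, "ndvi": 1.0, "diversity": 1.5,
    },
}

CONTINUOUS_LAYERS = ("elevation", "dist_road", "lst", "ndvi", "diversity", "hli")

#: Plausible output ranges for the rescaled base layers.
_LAYER_RANGES = {"elevation": (113.0, 3317.0), "lst": (289.6, 323.0),
                 "ndvi": (-0.17, 0.84), "hli": (0.3, 1.12)}


@dataclass
class LandscapeSpec:
    """Generating parameters for one synthetic study landscape."""

    shape: tuple[int, int] = (128, 128)
    cell_size: float = 500.0
    seed: int = 0
    n_landuse_classes: int = 8
    smoothness: float = 8.0        # correlation length, in cells
    season_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_SEASON_EFFECTS.items()})
    risk_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS))
    species_coefficients: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_SPECIES_COEFFICIENTS.items()})
    crs_tag: str = "EPSG:32638"
    origin: tuple[float, float] = (500_000.0, 3_900_000.0)

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise GridValidationError("landscape must be at least 16x16 cells")
        if not 2 <= self.n_landuse_classes <= 26:
            raise GridValidationError("n_landuse_classes must be in [2, 26]")
        known = set(CONTINUOUS_LAYERS) | {"intercept"}
        for name, coefs in [("risk_coefficients", self.risk_coefficients),
                            *[(f"species {s}", c) for s, c in self.species_coefficients.items()]]:
            unknown = set(coefs) - known
            if unknown:
                raise GridValidationError(
                    f"{name} references unknown layers {sorted(unknown)}; "
                    f"generated layers are {CONTINUOUS_LAYERS}")


@dataclass
class GroundTruth:
    """True generating surfaces: the oracle for recovery tests."""

    risk_surface: dict[str, RasterGrid]                 # per season
    suitability_surface: dict[str, RasterGrid]          # per species
    risk_coefficients: Mapping[str, float]
    species_coefficients: Mapping[str, Mapping[str, float]]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Gaussian-smoothed white noise, re-standardized to mean 0 / sd 1."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    return (f - f.mean()) / f.std()


def _rescale(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = f.min(), f.max()
    return lo + (f - fmin) * (hi - lo) / (fmax - fmin)


def _road_mask(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Rasterized polylines: a few random walks crossing the grid."""
    nrow, ncol = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(2):
        r = int(rng.integers(nrow // 4, 3 * nrow // 4))
        c = 0
        while c < ncol:
            mask[r, c] = True
            c += 1
            r = int(np.clip(r + rng.integers(-1, 2), 0, nrow - 1))
    for _ in range(1):
        c = int(rng.integers(ncol // 4, 3 * ncol // 4))
        r = 0
        while r < nrow:
            mask[r, c] = True
            r += 1
            c = int(np.clip(c + rng.integers(-1, 2), 0, ncol - 1))
    return mask


def _standardize_valid(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _logistic_surface(layers: Mapping[str, np.ndarray],
                      coefs: Mapping[str, float]) -> np.ndarray:
    eta = np.full(next(iter(layers.values())).shape, float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        eta += beta * _standardize_valid(layers[name])
    return 1.0 / (1.0 + np.exp(-eta))


def make_landscape(spec: LandscapeSpec) -> tuple[dict[str, RasterStack], RasterGrid, GroundTruth]:
    """Generate per-season covariate stacks, a land-use map and ground truth.

    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    no_mask = np.zeros(shape, dtype=bool)

    def grid(values: np.ndarray, legend=None) -> RasterGrid:
        return RasterGrid(values, no_mask.copy(), spec.cell_size, spec.origin,
                          spec.crs_tag, legend)

    elevation = _rescale(_smooth_field(rng, shape, spec.smoothness), *_LAYER_RANGES["elevation"])
    lst_base = _rescale(_smooth_field(rng, shape, spec.smoothness), *_LAYER_RANGES["lst"])
    ndvi_base = _rescale(_smooth_field(rng, shape, spec.smoothness), *_LAYER_RANGES["ndvi"])
    hli = _rescale(_smooth_field(rng, shape, max(2.0, spec.smoothness / 2)), *_LAYER_RANGES["hli"])

    roads = _road_mask(rng, shape)
    dist_road = ndimage.distance_transform_edt(~roads) * spec.cell_size

    landuse = _make_landuse(rng, spec, elevation)
    diversity_grid = window_diversity(grid(landuse.values, landuse.legend), window=5)

    stacks: dict[str, RasterStack] = {}
    season_layers: dict[str, dict[str, np.ndarray]] = {}
    for season in SEASONS:
        effects = spec.season_effects.get(season, {})
        layers = {
            "elevation": elevation,
            "dist_road": dist_road,
            "lst": lst_base + float(effects.get("lst", 0.0)),
            "ndvi": ndvi_base + float(effects.get("ndvi", 0.0)),
            "diversity": diversity_grid.values,
            "hli": hli,
        }
        season_layers[season] = layers
        stacks[season] = RasterStack(
            [grid(layers[name].astype(float)) for name in CONTINUOUS_LAYERS],
            list(CONTINUOUS_LAYERS),
        )

    risk = {season: grid(_logistic_surface(season_layers[season], spec.risk_coefficients))
            for season in SEASONS}
    # Habitat suitability is modelled as season-stable; spring covariates
    # define the standardization baseline.
    suitability = {
        species: grid(_logistic_surface(season_layers["spring"], coefs))
        for species, coefs in spec.species_coefficients.items()
    }
    truth = GroundTruth(risk, suitability, dict(spec.risk_coefficients),
                        {s: dict(c) for s, c in spec.species_coefficients.items()})
    return stacks, landuse, truth


def _make_landuse(rng: np.random.Generator, spec: LandscapeSpec,
                  elevation: np.ndarray) -> RasterGrid:
    """Categorical map from quantile-sliced smooth noise, with an
    agriculture class stamped preferentially at low elevation so land-use
    cross-tabs of fire points have structure."""
    k = spec.n_landuse_classes
    f = _smooth_field(rng, tuple(spec.shape), spec.smoothness)
    edges = np.quantile(f, np.linspace(0, 1, k + 1)[1:-1])
    codes = np.digitize(f, edges).astype(np.int32) + 1  # classes 1..k
    agri_code = 1
    low = elevation < np.quantile(elevation, 0.35)
    stamp = low & (_smooth_field(rng, tuple(spec.shape), spec.smoothness / 2) > 0)
    codes[stamp] = agri_code
    names = ["agriculture", "rainfed_agriculture", "rangeland", "dense_forest",
             "open_forest", "urban", "bare", "water"]
    legend = {i + 1: (names[i] if i < len(names) else f"class_{i + 1}") for i in range(k)}
    return RasterGrid(codes, np.zeros(spec.shape, dtype=bool), spec.cell_size,
                      spec.origin, spec.crs_tag, legend)


def _sample_cells(surface: RasterGrid, n: int, rng: np.random.Generator,
                  replace: bool) -> tuple[np.ndarray, np.ndarray]:
    p = np.where(surface.valid, surface.values, 0.0).ravel()
    positive = int((p > 0).sum())
    if not replace and n > positive:
        raise GridValidationError(
            f"cannot draw {n} distinct cells: only {positive} cells have positive probability")
    idx = rng.choice(p.size, size=n, replace=replace, p=p / p.sum())
    return np.unravel_index(idx, surface.shape)


def sample_presences(truth: GroundTruth, n: int, season: str, seed: int,
                     replace: bool = False) -> OccurrenceSet:
    """Draw presence cells with probability proportional to true fire risk.

    Cells are drawn without replacement by default (``replace=True`` is a
    test mode for frequency checks); points sit at cell centers.
    """
    if n < 1:
        raise GridValidationError("n must be >= 1")
    if season not in truth.risk_surface:
        raise GridValidationError(f"unknown season {season!r}")
    surface = truth.risk_surface[season]
    rng = np.random.default_rng(seed)
    rows, cols = _sample_cells(surface, n, rng, replace)
    x, y = surface.cell_center(rows, cols)
    return OccurrenceSet.from_records(
        [(float(xi), float(yi), season, "presence", "synthetic_fire")
         for xi, yi in zip(x, y)])


def sample_habitat_presences(truth: GroundTruth, n: int, species: str, seed: int,
                             season: str = "spring") -> OccurrenceSet:
    """Draw species presence cells proportional to true habitat suitability."""
    if n < 1:
        raise GridValidationError("n must be >= 1")
    if species not in truth.suitability_surface:
        raise GridValidationError(
            f"unknown species {species!r}; have {sorted(truth.suitability_surface)}")
    surface = truth.suitability_surface[species]
    rng = np.random.default_rng(seed)
    rows, cols = _sample_cells(surface, n, rng, replace=False)
    x, y = surface.cell_center(rows, cols)
    return OccurrenceSet.from_records(
        [(float(xi), float(yi), season, "presence", f"synthetic_{species}")
         for xi, yi in zip(x, y)])
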