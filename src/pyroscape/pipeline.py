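"""End-to-end orchestration of the synthetic seasonal fire/habitat study.

``run_all`` wires the stages together for each season and species:

    simulate -> thin -> screen -> two-step pseudo-absence -> classifier
    suite -> ensemble probability map -> TSS binarization -> seasonal
    change surfaces -> habitat x fire GAP overlap

and writes every artifact (GeoTIFFs, CSVs, a JSON manifest with seeds,
stage record counts and output hashes) into one output directory, so a run
is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_model import (ClassifierEnsemble, ensemble_test_auc, fit_suite,
                             predict_ensemble, predict_table, split_table,
                             variable_importance)
from .evaluation import binarize, tss_threshold
from .grid_io import (OccurrenceSet, RasterGrid, RasterStack, SEASONS,
                      extract_at_points, write_points, write_raster)
from .overlap import gap_overlap
from .preprocess import correlation_screen, crosstab_landuse, thin_points
from .pseudo_absence import two_step_pseudo_absence
from .seasonal_change import change_index
from .synthetic_landscape import (LandscapeSpec, make_landscape,
                                  sample_habitat_presences, sample_presences)


def derive_seed(base: int, *tags) -> int:
    """Deterministic per-stage seed below 2**31, derived from a base seed
    and a sequence of stage tags."""
    digest = hashlib.sha256(("/".join(map(str, (base, *tags)))).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """All tunables of one study run; numeric defaults are the protocol's
    stated values (1 km / 300 m thinning, |r| cutoffs 0.85 / 0.75, AUC
    gate 0.8, 2x pseudo-absences, 70/30 split)."""

    seed: int = 0
    out_dir: str = "pyroscape_run"
    seasons: tuple[str, ...] = SEASONS
    n_fire_presences: int = 300
    n_species_presences: int = 300
    fire_thin_distance: float = 300.0
    species_thin_distance: float = 1000.0
    fire_corr_threshold: float = 0.75
    species_corr_threshold: float = 0.85
    auc_gate: float = 0.8
    pseudo_absence_multiplier: int = 2
    train_fraction: float = 0.7
    fire_registry: str = "fire6"
    sdm_registry: str = "sdm8"
    weight_mode: str = "auc"
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        land = raw.pop("landscape", {})
        if "shape" in land:
            land["shape"] = tuple(land["shape"])
        if "origin" in land:
            land["origin"] = tuple(land["origin"])
        cfg = cls(**{k: v for k, v in raw.items() if k != "landscape"})
        if "seasons" in raw:
            cfg.seasons = tuple(raw["seasons"])
        cfg.landscape = LandscapeSpec(**land) if land else LandscapeSpec(seed=cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class SeasonResult:
    season: str
    screened_layers: list[str]
    ensemble: ClassifierEnsemble
    probability: RasterGrid
    binary: RasterGrid
    report: dict
    importance: pd.DataFrame
    n_presence_raw: int
    n_presence_thinned: int
    n_pseudo: int


def run_fire_season(stacks, truth, config: RunConfig, season: str,
                    log: list[str]) -> SeasonResult:
    """Fire-susceptibility modelling for one season."""
    seed = config.seed
    presences = sample_presences(
        truth, config.n_fire_presences, season, derive_seed(seed, season, "sample"))
    thinned = thin_points(presences, config.fire_thin_distance)
    log.append(f"[{season}] thinning: {len(presences)} -> {len(thinned)} presences")

    stack = stacks[season]
    extraction = extract_at_points(stack, thinned)
    screen = correlation_screen(extraction.features, config.fire_corr_threshold)
    log.append(f"[{season}] screening (|r|>{config.fire_corr_threshold}): "
               f"kept {screen.kept}, dropped {[d[0] for d in screen.dropped]}")
    sub = stack.subset(screen.kept)

    ensemble_po, pseudo = two_step_pseudo_absence(
        sub, thinned, seed=derive_seed(seed, season, "pseudo"),
        gate=config.auc_gate, multiplier=config.pseudo_absence_multiplier,
        train_fraction=config.train_fraction, season=season)
    log.append(f"[{season}] presence-only members passing gate: {ensemble_po.passing}; "
               f"{len(pseudo)} pseudo-absences sampled")

    merged = thinned.concat(pseudo)
    feats = extract_at_points(sub, merged)
    labels = (merged.table["label"].iloc[feats.kept_index] == "presence").to_numpy(int)
    table = split_table(feats.features.reset_index(drop=True), labels,
                        config.train_fraction, derive_seed(seed, season, "split"))
    suite = fit_suite(table, config.fire_registry,
                      seed=derive_seed(seed, season, "fit"),
                      weight_mode=config.weight_mode, log=log)
    prob = predict_ensemble(suite, sub)
    x_test, y_test = table.part("test")
    thr, report = tss_threshold(predict_table(suite, x_test), y_test, tag=season)
    report.auc = ensemble_test_auc(suite, table)
    binary = binarize(prob, thr)
    importance = variable_importance(table, seed=derive_seed(seed, season, "imp"),
                                     tag=season)
    return SeasonResult(season, screen.kept, suite, prob, binary,
                        report.as_dict(), importance.table,
                        len(presences), len(thinned), len(pseudo))


@dataclass
class SpeciesResult:
    species: str
    ensemble: ClassifierEnsemble
    probability: RasterGrid
    binary: RasterGrid
    report: dict
    n_presence_thinned: int


def run_species(stacks, truth, config: RunConfig, species: str,
                log: list[str]) -> SpeciesResult:
    """Habitat-suitability modelling for one focal species (season-stable
    habitat; spring covariates)."""
    seed = config.seed
    presences = sample_habitat_presences(
        truth, config.n_species_presences, species, derive_seed(seed, species, "sample"))
    thinned = thin_points(presences, config.species_thin_distance)
    log.append(f"[{species}] thinning: {len(presences)} -> {len(thinned)} presences")

    stack = stacks["spring"]
    extraction = extract_at_points(stack, thinned)
    screen = correlation_screen(extraction.features, config.species_corr_threshold)
    sub = stack.subset(screen.kept)

    # uniform random background at 2:1, avoiding presence cells
    rng = np.random.default_rng(derive_seed(seed, species, "background"))
    grid = sub.grid
    candidates = sub.valid_mask()
    xy = thinned.xy()
    r, c = grid.cell_of(xy[:, 0], xy[:, 1])
    candidates[r, c] = False
    idx = np.flatnonzero(candidates.ravel())
    n_bg = 2 * len(thinned)
    chosen = rng.choice(idx, size=n_bg, replace=False)
    rows, cols = np.unravel_index(chosen, grid.shape)
    bx, by = grid.cell_center(rows, cols)
    background = OccurrenceSet.from_records(
        [(float(xi), float(yi), "spring", "pseudo_absence", "uniform_background")
         for xi, yi in zip(bx, by)])

    merged = thinned.concat(background)
    feats = extract_at_points(sub, merged)
    labels = (merged.table["label"].iloc[feats.kept_index] == "presence").to_numpy(int)
    table = split_table(feats.features.reset_index(drop=True), labels,
                        config.train_fraction, derive_seed(seed, species, "split"))
    suite = fit_suite(table, config.sdm_registry,
                      seed=derive_seed(seed, species, "fit"),
                      weight_mode=config.weight_mode, log=log)
    prob = predict_ensemble(suite, sub)
    x_test, y_test = table.part("test")
    thr, report = tss_threshold(predict_table(suite, x_test), y_test, tag=species)
    report.auc = ensemble_test_auc(suite, table)
    binary = binarize(prob, thr)
    return SpeciesResult(species, suite, prob, binary, report.as_dict(), len(thinned))


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic study; returns the manifest dict.

    Any stage failure aborts with the stage name; a partial manifest is
    written to the output directory before the exception propagates.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "landscape"},
        "landscape": asdict(config.landscape),
        "stages": [], "records": {}, "outputs": {}, "log": log,
    }
    stage = "simulate"
    try:
        land_spec = config.landscape
        stacks, landuse, truth = make_landscape(land_spec)
        manifest["stages"].append(stage)
        write_raster(landuse, out / "landuse.tif")

        season_results: dict[str, SeasonResult] = {}
        reports = []
        for season in config.seasons:
            stage = f"fire:{season}"
            res = run_fire_season(stacks, truth, config, season, log)
            season_results[season] = res
            manifest["stages"].append(stage)
            manifest["records"][stage] = {
                "presences_raw": res.n_presence_raw,
                "presences_thinned": res.n_presence_thinned,
                "pseudo_absences": res.n_pseudo,
                "layers_kept": res.screened_layers,
                "member_aucs": res.ensemble.member_aucs(),
            }
            write_raster(res.probability, out / f"fire_probability_{season}.tif")
            write_raster(res.binary, out / f"fire_binary_{season}.tif")
            res.importance.to_csv(out / f"importance_{season}.csv", index=False)
            reports.append(res.report)

            stage = f"crosstab:{season}"
            pres = sample_presences(truth, config.n_fire_presences, season,
                                    derive_seed(config.seed, season, "sample"))
            ct = crosstab_landuse(thin_points(pres, config.fire_thin_distance), landuse)
            ct.table.to_csv(out / f"crosstab_{season}.csv", index=False)
            manifest["stages"].append(stage)
        pd.DataFrame(reports).to_csv(out / "fire_validation.csv", index=False)

        stage = "seasonal_change"
        pairs = list(zip(config.seasons[:-1], config.seasons[1:]))
        for a, b in pairs:
            if a in season_results and b in season_results:
                cm = change_index(season_results[a].probability,
                                  season_results[b].probability, f"{a}->{b}")
                write_raster(cm.index, out / f"change_{a}_{b}.tif")
        manifest["stages"].append(stage)

        species_results: dict[str, SpeciesResult] = {}
        sp_reports = []
        for species in truth.suitability_surface:
            stage = f"sdm:{species}"
            res = run_species(stacks, truth, config, species, log)
            species_results[species] = res
            manifest["stages"].append(stage)
            manifest["records"][stage] = {
                "presences_thinned": res.n_presence_thinned,
                "member_aucs": res.ensemble.member_aucs(),
            }
            write_raster(res.probability, out / f"habitat_probability_{species}.tif")
            write_raster(res.binary, out / f"habitat_binary_{species}.tif")
            sp_reports.append(res.report)
        pd.DataFrame(sp_reports).to_csv(out / "sdm_validation.csv", index=False)

        stage = "overlap"
        overlap_rows = []
        for species, sres in species_results.items():
            for season, fres in season_results.items():
                class_grid, summary = gap_overlap(sres.binary, fres.binary,
                                                  species=species, season=season)
                write_raster(class_grid, out / f"overlap_{species}_{season}.tif")
                overlap_rows.append(summary.as_dict())
        pd.DataFrame(overlap_rows).to_csv(out / "overlap_summary.csv", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
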