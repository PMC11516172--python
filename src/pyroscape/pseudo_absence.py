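"""Two-step pseudo-absence selection for presence-only fire data.

Classification needs two labels, but satellite fire archives only record
where fire *was*.  The two-step remedy: (1) fit presence-only models — a
climatic envelope (Bioclim-style), a Gower-similarity model (Domain-style)
and a one-class support-vector novelty detector — and keep those whose
test AUC clears a gate (default 0.8); (2) combine the survivors' binary
maps by majority vote and sample pseudo-absences uniformly from the region
every passing model scores as no-risk.  The pseudo-absence count defaults
to twice the presence count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .grid_io import (GridValidationError, OccurrenceSet, RasterGrid, RasterStack,
                      extract_at_points)
from .evaluation import auc as _rank_auc


class ModelFitError(ValueError):
    """A presence-only model cannot be fitted on the given data."""


# ---------------------------------------------------------------------------
# Presence-only members
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeModel:
    """Climatic-envelope model: suitable iff every variable lies inside the
    per-variable [lower, upper] percentile bounds of the presences.

    Trim defaults to 0/100 (strict min/max envelope); 5/95 is the common
    robust alternative.
    """

    variables: list[str]
    lower: np.ndarray
    upper: np.ndarray
    trim: tuple[float, float]

    @classmethod
    def fit(cls, presence_features: pd.DataFrame,
            trim: tuple[float, float] = (0.0, 100.0)) -> "EnvelopeModel":
        if len(presence_features) < 5:
            raise ModelFitError("envelope model needs >= 5 presence rows")
        lo_q, hi_q = trim
        if not 0 <= lo_q < hi_q <= 100:
            raise ModelFitError("trim percentiles must satisfy 0 <= lo < hi <= 100")
        x = presence_features.to_numpy(float)
        return cls(list(presence_features.columns),
                   np.percentile(x, lo_q, axis=0),
                   np.percentile(x, hi_q, axis=0), trim)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.variables].to_numpy(float)
        inside = (x >= self.lower) & (x <= self.upper)
        return inside.all(axis=1).astype(int)


@dataclass
class DomainModel:
    """Gower-similarity model: similarity to presence i is
    1 - mean_v |x_v - p_iv| / range_v; a cell is suitable iff its maximum
    similarity over presences reaches the threshold theta (default 0.95,
    the conventional cutoff)."""

    variables: list[str]
    presences: np.ndarray
    ranges: np.ndarray
    theta: float
    excluded_zero_range: list[str]

    @classmethod
    def fit(cls, presence_features: pd.DataFrame, theta: float = 0.95) -> "DomainModel":
        if not 0 < theta <= 1:
            raise ModelFitError("theta must lie in (0, 1]")
        if len(presence_features) < 5:
            raise ModelFitError("domain model needs >= 5 presence rows")
        x = presence_features.to_numpy(float)
        ranges = x.max(axis=0) - x.min(axis=0)
        usable = ranges > 0
        if not usable.any():
            raise ModelFitError("all variables have zero range across presences")
        excluded = [c for c, u in zip(presence_features.columns, usable) if not u]
        cols = [c for c, u in zip(presence_features.columns, usable) if u]
        return cls(cols, x[:, usable], ranges[usable], theta, excluded)

    def similarity(self, features: pd.DataFrame, chunk: int = 2048) -> np.ndarray:
        x = features[self.variables].to_numpy(float)
        out = np.empty(len(x))
        for start in range(0, len(x), chunk):
            block = x[start:start + chunk]
            diff = np.abs(block[:, None, :] - self.presences[None, :, :]) / self.ranges
            out[start:start + chunk] = 1.0 - diff.mean(axis=2).min(axis=1)
        return out

    def score(self, features: pd.DataFrame) -> np.ndarray:
        return (self.similarity(features) >= self.theta).astype(int)


@dataclass
class NoveltyModel:
    """One-class SVM novelty detector on standardized features: inlier -> 1."""

    variables: list[str]
    scaler: StandardScaler
    svm: OneClassSVM

    @classmethod
    def fit(cls, presence_features: pd.DataFrame, nu: float = 0.1,
            gamma: str | float = "scale") -> "NoveltyModel":
        if len(presence_features) < 10:
            raise ModelFitError("novelty model needs >= 10 presence rows")
        x = presence_features.to_numpy(float)
        if np.any(x.std(axis=0) == 0):
            raise ModelFitError("constant feature(s); drop them before fitting")
        scaler = StandardScaler().fit(x)
        svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma).fit(scaler.transform(x))
        return cls(list(presence_features.columns), scaler, svm)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        z = self.scaler.transform(features[self.variables].to_numpy(float))
        return (self.svm.predict(z) == 1).astype(int)


# ---------------------------------------------------------------------------
# Evaluation and combination
# ---------------------------------------------------------------------------

def evaluate_binary_auc(scores, labels) -> float:
    """Rank-based AUC with ties counted 1/2; for binary scores this equals
    (sensitivity + specificity) / 2 against the negative group."""
    return _rank_auc(scores, labels)


@dataclass
class PresenceOnlyEnsemble:
    """Gated presence-only members and their combined binary map."""

    members: list[tuple[str, RasterGrid, float]]  # (tag, binary map, test AUC)
    gate: float
    combined: RasterGrid
    zero_region: RasterGrid  # boolean: candidate pseudo-absence zone

    @property
    def passing(self) -> list[str]:
        return [tag for tag, _, a in self.members if a > self.gate]


def combine_presence_only(members: list[tuple[str, RasterGrid, float]],
                          gate: float = 0.8) -> PresenceOnlyEnsemble:
    """Majority vote of members whose AUC clears the gate; ties vote 1
    (risk-conservative: a doubtful cell is kept out of the pseudo-absence
    pool rather than contaminating it)."""
    passing = [(tag, m, a) for tag, m, a in members if a > gate]
    if not passing:
        aucs = {tag: round(a, 3) for tag, _, a in members}
        raise ModelFitError(
            f"no presence-only member cleared the AUC gate {gate}; member AUCs: {aucs}. "
            "Inspect model inputs before sampling pseudo-absences.")
    ref = passing[0][1]
    votes = np.zeros(ref.shape, dtype=float)
    valid = np.ones(ref.shape, dtype=bool)
    for _, m, _ in passing:
        if not m.aligned_with(ref):
            raise GridValidationError("member maps are not aligned")
        votes += np.where(m.valid, m.values, 0)
        valid &= m.valid
    combined_vals = (votes >= len(passing) / 2.0).astype(np.int8)
    combined = ref.like(combined_vals, nodata_mask=~valid)
    zero = ref.like(((combined_vals == 0) & valid).astype(np.int8), nodata_mask=~valid)
    return PresenceOnlyEnsemble(members, gate, combined, zero)


def sample_pseudo_absences(zero_region: RasterGrid, n_presence: int, seed: int,
                           multiplier: int = 2, season: str = "spring",
                           presence_points: OccurrenceSet | None = None) -> OccurrenceSet:
    """Uniform draw (without replacement) of multiplier * n_presence cells
    from the zero-risk region; points at cell centers, labelled
    ``pseudo_absence``.  Cells holding a presence point are never drawn."""
    n_needed = multiplier * n_presence
    candidates = (zero_region.values.astype(bool)) & zero_region.valid
    if presence_points is not None and len(presence_points):
        xy = presence_points.xy()
        r, c = zero_region.cell_of(xy[:, 0], xy[:, 1])
        nrow, ncol = zero_region.shape
        inb = (r >= 0) & (r < nrow) & (c >= 0) & (c < ncol)
        candidates[r[inb], c[inb]] = False
    idx = np.flatnonzero(candidates.ravel())
    if idx.size < n_needed:
        raise GridValidationError(
            f"zero region has {idx.size} candidate cells, need {n_needed} "
            f"(shortfall {n_needed - idx.size})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_needed, replace=False)
    rows, cols = np.unravel_index(chosen, zero_region.shape)
    x, y = zero_region.cell_center(rows, cols)
    return OccurrenceSet.from_records(
        [(float(xi), float(yi), season, "pseudo_absence", "two_step_sampler")
         for xi, yi in zip(x, y)])


# ---------------------------------------------------------------------------
# Full two-step driver
# ---------------------------------------------------------------------------

def two_step_pseudo_absence(stack: RasterStack, presences: OccurrenceSet,
                            seed: int, gate: float = 0.8, multiplier: int = 2,
                            train_fraction: float = 0.7,
                            envelope_trim: tuple[float, float] = (0.0, 100.0),
                            domain_theta: float = 0.95,
                            season: str | None = None,
                            ) -> tuple[PresenceOnlyEnsemble, OccurrenceSet]:
    """Run the whole two-step procedure for one season.

    Presences are split 70/30; each presence-only model is fitted on the
    training share and scored by AUC on the held-out presences against an
    equal-size uniform random background.  Members clearing the gate are
    majority-vote combined; pseudo-absences are sampled from the combined
    zero region.
    """
    rng = np.random.default_rng(seed)
    season = season or (presences.table["season"].iloc[0] if len(presences) else "spring")
    extraction = extract_at_points(stack, presences)
    feats = extraction.features.reset_index(drop=True)
    n = len(feats)
    if n < 15:
        raise ModelFitError(f"need >= 15 usable presences, have {n}")
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = feats.iloc[order[:n_train]]
    test = feats.iloc[order[n_train:]]

    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    cell_feats = pd.DataFrame(
        {name: layer.values[rows, cols] for name, layer in zip(stack.names, stack.layers)})

    # background for testing: uniform random valid cells, as many as test presences
    bg_idx = rng.choice(len(cell_feats), size=len(test), replace=False)
    background = cell_feats.iloc[bg_idx]

    grid = stack.grid
    members: list[tuple[str, RasterGrid, float]] = []
    fitted = {
        "envelope": EnvelopeModel.fit(train, trim=envelope_trim),
        "domain": DomainModel.fit(train, theta=domain_theta),
        "novelty": NoveltyModel.fit(train),
    }
    for tag, model in fitted.items():
        test_scores = np.concatenate([model.score(test), model.score(background)])
        labels = np.concatenate([np.ones(len(test)), np.zeros(len(background))])
        member_auc = evaluate_binary_auc(test_scores, labels)
        full = np.zeros(grid.shape, dtype=np.int8)
        full[rows, cols] = model.score(cell_feats)
        members.append((tag, grid.like(full, nodata_mask=~valid), float(member_auc)))

    ensemble = combine_presence_only(members, gate=gate)
    pseudo = sample_pseudo_absences(
        ensemble.zero_region, n, seed=int(rng.integers(2**31 - 1)),
        multiplier=multiplier, season=season, presence_points=presences)
    return ensemble, pseudo
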