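"""Presence / pseudo-absence classifier suites and AUC-weighted ensembling.

Two learner registries mirror the two modelling stages:

* ``fire6`` — the wildfire-susceptibility suite: random forest, single
  classification tree, adaptive-spline logistic model, gradient-boosted
  trees, elastic-net-regularized logistic path, and plain logistic
  regression.
* ``sdm8`` — the species-distribution suite: logistic GLM, spline-basis
  additive logistic model (GAM-style), adaptive splines, gradient-boosted
  trees, classification tree, random forest, single-hidden-layer neural
  net, and a kernel max-margin classifier.

Each fitted member is weighted by its test AUC; the ensemble probability
map is the normalized AUC-weighted mean of member probability maps.
Variable importance is permutation importance (AUC drop) on the test
partition under a bagged-tree learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import auc
from .grid_io import GridValidationError, RasterGrid, RasterStack


class EnsembleError(ValueError):
    pass


@dataclass
class TrainingTable:
    """Features + binary labels with a frozen stratified train/test split."""

    features: pd.DataFrame
    labels: np.ndarray
    split: np.ndarray  # "train" / "test" per row
    split_seed: int

    def part(self, which: str) -> tuple[pd.DataFrame, np.ndarray]:
        m = self.split == which
        return self.features[m], self.labels[m]


def split_table(features: pd.DataFrame, labels, train_fraction: float = 0.7,
                seed: int = 0) -> TrainingTable:
    """Stratified 70/30 (by default) split, reproducible under seed."""
    labels = np.asarray(labels, int)
    for cls in (0, 1):
        if (labels == cls).sum() < 10:
            raise EnsembleError(f"need >= 10 rows of class {cls}")
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)), train_size=train_fraction,
        stratify=labels, random_state=seed)
    split = np.full(len(labels), "train", dtype=object)
    split[idx_test] = "test"
    for which in ("train", "test"):
        part = labels[split == which]
        if not ((part == 1).any() and (part == 0).any()):
            raise EnsembleError(f"class missing from {which} partition")
    return TrainingTable(features.reset_index(drop=True), labels, split, seed)


# ---------------------------------------------------------------------------
# Learner registries
# ---------------------------------------------------------------------------

def _spline_logistic(seed: int, n_knots: int = 5) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("spline", SplineTransformer(n_knots=n_knots, degree=3)),
        ("logit", LogisticRegression(max_iter=2000, random_state=seed)),
    ])


def _scaled_logistic(seed: int, **kw) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("logit", LogisticRegression(max_iter=2000, random_state=seed, **kw)),
    ])


def fire6_registry(seed: int) -> dict[str, object]:
    return {
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "cta": DecisionTreeClassifier(random_state=seed),
        "mars": _spline_logistic(seed),
        "gbt": GradientBoostingClassifier(random_state=seed),
        "enet_path": _scaled_logistic(seed, solver="saga", l1_ratio=0.5, C=1.0),
        "logistic": _scaled_logistic(seed),
    }


def sdm8_registry(seed: int) -> dict[str, object]:
    return {
        "glm": _scaled_logistic(seed),
        "gam": _spline_logistic(seed, n_knots=8),
        "mars": _spline_logistic(seed, n_knots=5),
        "gbt": GradientBoostingClassifier(random_state=seed),
        "cta": DecisionTreeClassifier(random_state=seed),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "ann": Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(16,), max_iter=1000,
                                  random_state=seed)),
        ]),
        "svm": Pipeline([
            ("scale", StandardScaler()),
            ("svc", CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)),
        ]),
    }


REGISTRIES: dict[str, Callable[[int], dict[str, object]]] = {
    "fire6": fire6_registry,
    "sdm8": sdm8_registry,
}


@dataclass
class ClassifierEnsemble:
    """Fitted members with AUC weights; predicts a probability raster."""

    members: list[tuple[str, object, float]]  # (tag, fitted model, test AUC)
    feature_names: list[str]
    registry: str

    @property
    def weights(self) -> np.ndarray:
        w = np.array([a for _, _, a in self.members], float)
        return w / w.sum()

    def member_aucs(self) -> dict[str, float]:
        return {tag: a for tag, _, a in self.members}


def fit_suite(table: TrainingTable, registry: str = "fire6",
              seed: int = 0, weight_mode: str = "auc",
              log: list[str] | None = None) -> ClassifierEnsemble:
    """Fit every registry learner on the train partition; weight by test AUC.

    Learners that fail to fit are dropped with a logged warning; fewer than
    two survivors is an error.  ``weight_mode='auc-excess'`` weights by
    max(AUC - 0.5, 0) instead of raw AUC.
    """
    if registry not in REGISTRIES:
        raise EnsembleError(f"unknown registry {registry!r}; have {sorted(REGISTRIES)}")
    if weight_mode not in ("auc", "auc-excess"):
        raise EnsembleError(f"unknown weight_mode {weight_mode!r}")
    x_train, y_train = table.part("train")
    x_test, y_test = table.part("test")
    members: list[tuple[str, object, float]] = []
    for tag, model in REGISTRIES[registry](seed).items():
        try:
            model.fit(x_train.to_numpy(float), y_train)
            p = model.predict_proba(x_test.to_numpy(float))[:, 1]
            member_auc = auc(p, y_test)
        except Exception as exc:  # noqa: BLE001 — any learner failure drops it
            if log is not None:
                log.append(f"learner {tag} dropped: {exc}")
            continue
        w = member_auc if weight_mode == "auc" else max(member_auc - 0.5, 0.0)
        if w <= 0:
            if log is not None:
                log.append(f"learner {tag} dropped: non-positive weight {w}")
            continue
        members.append((tag, model, float(w)))
    if len(members) < 2:
        raise EnsembleError(f"only {len(members)} learner(s) survived; need >= 2")
    return ClassifierEnsemble(members, list(table.features.columns), registry)


def ensemble_test_auc(ensemble: ClassifierEnsemble, table: TrainingTable) -> float:
    x_test, y_test = table.part("test")
    p = predict_table(ensemble, x_test)
    return auc(p, y_test)


def predict_table(ensemble: ClassifierEnsemble, features: pd.DataFrame) -> np.ndarray:
    x = features[ensemble.feature_names].to_numpy(float)
    w = ensemble.weights
    out = np.zeros(len(features))
    for (tag, model, _), wi in zip(ensemble.members, w):
        out += wi * model.predict_proba(x)[:, 1]
    return out


def predict_ensemble(ensemble: ClassifierEnsemble, stack: RasterStack) -> RasterGrid:
    """AUC-weighted mean probability over the stack; nodata propagates."""
    missing = [n for n in ensemble.feature_names if n not in stack]
    if missing:
        raise EnsembleError(f"stack lacks layer(s) {missing}")
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    feats = pd.DataFrame(
        {name: stack[name].values[rows, cols] for name in ensemble.feature_names})
    probs = predict_table(ensemble, feats)
    out = np.zeros(stack.grid.shape)
    out[rows, cols] = probs
    return stack.grid.like(out, nodata_mask=~valid)


@dataclass
class ImportanceTable:
    """Normalized permutation-importance weights per variable."""

    table: pd.DataFrame  # columns: variable, weight
    tag: str = ""


def variable_importance(table: TrainingTable, seed: int = 0,
                        n_repeats: int = 10, tag: str = "") -> ImportanceTable:
    """Permutation importance on the test partition under a random forest.

    Importance of a variable = mean drop in test AUC over ``n_repeats``
    permutations of that column, floored at 0 and normalized to sum 1.
    """
    rng = np.random.default_rng(seed)
    x_train, y_train = table.part("train")
    x_test, y_test = table.part("test")
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf.fit(x_train.to_numpy(float), y_train)
    base = auc(rf.predict_proba(x_test.to_numpy(float))[:, 1], y_test)
    x = x_test.to_numpy(float)
    drops = []
    for j, name in enumerate(table.features.columns):
        deltas = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(len(xp)), j]
            deltas.append(base - auc(rf.predict_proba(xp)[:, 1], y_test))
        drops.append(max(float(np.mean(deltas)), 0.0))
    drops = np.array(drops)
    # importance is only attributable when the learner has skill: near-chance
    # base AUC (or an all-zero drop profile) yields the uniform profile
    # rather than normalized overfitting noise
    if base < 0.55 or drops.sum() < 1e-9:
        weights = np.full(len(drops), 1.0 / len(drops))
    else:
        weights = drops / drops.sum()
    return ImportanceTable(
        pd.DataFrame({"variable": list(table.features.columns), "weight": weights})
        .sort_values("weight", ascending=False).reset_index(drop=True), tag)
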