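"""Normalization, RBF-SVM training with grid search, and prediction.

Training z-scores every feature column (x* = (x - mu) / sigma, constant
columns map to 0), selects the RBF kernel width gamma and penalty C by
stratified cross-validated AUC over a grid, and fits a support vector
machine K(Xi, Xj) = exp(-gamma |Xi - Xj|^2) on the scaled matrix.  The
default gamma is 1 / (n_features * sigma2) with sigma2 the mean per-feature
variance of the scaled matrix (after z-scoring this is ~1, giving
gamma ~ 1/193).

Everything prediction needs — scaler parameters, potential tables, SVM
state, feature-manifest version, the grid-search record and the seed — is
bundled into one :class:`TrainedModel`, so scoring new data never
re-estimates anything fitted on training data (the leakage guard).  Scores
are a fixed logistic squashing of the SVM margin: monotone in the decision
value, so the predicted label (score >= 0.5) equals the margin's sign and
ranking metrics are unchanged by the mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigurationError, TrainingError
from .featurize import (
    FEATURE_NAMES,
    MANIFEST_VERSION,
    FeatureMatrix,
    N_FEATURES,
    featurize_many,
)
from .folding import fold
from .potentials import PotentialSet

DEFAULT_C_GRID = tuple(float(2.0 ** e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_EXPONENTS = tuple(range(-15, 4, 2))


@dataclass(frozen=True)
class ScalerParams:
    """Per-column z-score parameters fitted on training data only."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu/sigma shape mismatch")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive (constant columns map to 1)")


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Column-wise mean/std; the std of a constant column is replaced by 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise TrainingError("scaler needs at least 2 training rows")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma = np.where(sigma == 0, 1.0, sigma)
    return ScalerParams(mu=mu, sigma=sigma)


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.mu.shape[0]:
        raise ConfigurationError(
            f"matrix has {X.shape[1]} columns, scaler expects {params.mu.shape[0]}"
        )
    return (X - params.mu) / params.sigma


def generalized_variance(X_scaled: np.ndarray) -> float:
    """Mean per-feature variance of a (scaled) matrix."""
    return float(np.asarray(X_scaled, dtype=float).var(axis=0).mean())


def default_gamma(n: int, sigma2: float) -> float:
    """gamma = 1 / (n * sigma2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma2 <= 0:
        raise TrainingError("degenerate data: generalized variance is 0")
    return 1.0 / (n * sigma2)


def _check_matrix(X: np.ndarray, y: np.ndarray) -> None:
    if np.isnan(X).any():
        bad = np.where(np.isnan(X).any(axis=0))[0]
        names = [FEATURE_NAMES[i] if i < N_FEATURES else str(i) for i in bad[:5]]
        raise TrainingError(f"NaN feature values in column(s) {names}")
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class")


@dataclass
class TrainedModel:
    """A complete, self-contained prediction bundle."""

    scaler: ScalerParams
    svm: SVC
    C: float
    gamma: float
    tables: PotentialSet
    manifest_version: str
    grid_record: list
    seed: int
    engine: str = "auto"
    stem_pct_reading: str = "literal"

    def decision_values(self, fm: FeatureMatrix) -> np.ndarray:
        if fm.manifest_version != self.manifest_version:
            raise ConfigurationError(
                f"feature manifest {fm.manifest_version!r} does not match the "
                f"model's {self.manifest_version!r}"
            )
        return self.svm.decision_function(apply_scaler(self.scaler, fm.X))


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid_C=None,
    grid_gamma=None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[SVC, float, float, list]:
    """Grid-search an RBF SVC by mean stratified-CV AUC on a scaled matrix.

    Ties are broken toward smaller C, then smaller gamma.  Returns the
    refitted SVC, the selected (C, gamma) and the full grid record.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_matrix(X, y)
    if grid_C is None:
        grid_C = DEFAULT_C_GRID
    if grid_gamma is None:
        g0 = default_gamma(X.shape[1], generalized_variance(X))
        grid_gamma = (g0,) + tuple(float(2.0 ** e) for e in DEFAULT_GAMMA_EXPONENTS)
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise TrainingError("not enough samples per class for CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    record = []
    best = None
    for C in sorted(set(float(c) for c in grid_C)):
        for gamma in sorted(set(float(g) for g in grid_gamma)):
            aucs = []
            for train_idx, test_idx in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[train_idx], y[train_idx])
                dv = clf.decision_function(X[test_idx])
                aucs.append(roc_auc_score(y[test_idx], dv))
            mean_auc = float(np.mean(aucs))
            record.append({"C": C, "gamma": gamma, "cv_auc": mean_auc,
                           "fold_aucs": [float(a) for a in aucs]})
            # strict > keeps the first (smallest C, then gamma) on ties
            if best is None or mean_auc > best[0]:
                best = (mean_auc, C, gamma)
    _, C, gamma = best
    final = SVC(C=C, gamma=gamma, kernel="rbf")
    final.fit(X, y)
    return final, C, gamma, record


def train(
    fm: FeatureMatrix,
    y: np.ndarray,
    tables: PotentialSet,
    grid_C=None,
    grid_gamma=None,
    folds: int = 5,
    seed: int = 0,
    engine: str = "auto",
    stem_pct_reading: str = "literal",
) -> TrainedModel:
    """Fit scaler + grid-searched RBF SVM on a featurized training set."""
    if fm.manifest_version != MANIFEST_VERSION:
        raise ConfigurationError("feature matrix manifest version mismatch")
    y = np.asarray(y, dtype=int)
    scaler = fit_scaler(fm.X)
    Xs = apply_scaler(scaler, fm.X)
    svm, C, gamma, record = train_svm(
        Xs, y, grid_C=grid_C, grid_gamma=grid_gamma, folds=folds, seed=seed
    )
    return TrainedModel(
        scaler=scaler, svm=svm, C=C, gamma=gamma, tables=tables,
        manifest_version=fm.manifest_version, grid_record=record, seed=seed,
        engine=engine, stem_pct_reading=stem_pct_reading,
    )


def train_pipeline(
    pos_pairs: list,
    neg_pairs: list,
    grid_C=None,
    grid_gamma=None,
    folds: int = 5,
    seed: int = 0,
    engine: str = "auto",
    stem_pct_reading: str = "literal",
) -> TrainedModel:
    """End-to-end training from folded (Sequence, SecondaryStructure) sets.

    Trains the potential tables on the labelled sets, featurizes, then fits
    the scaler and SVM.  Everything estimated here is frozen in the bundle.
    """
    if not pos_pairs or not neg_pairs:
        raise TrainingError("both classes must be non-empty")
    tables = PotentialSet.train(pos_pairs, neg_pairs)
    fm = featurize_many(pos_pairs + neg_pairs, tables,
                        stem_pct_reading=stem_pct_reading)
    y = np.array([1] * len(pos_pairs) + [0] * len(neg_pairs))
    return train(fm, y, tables, grid_C=grid_C, grid_gamma=grid_gamma,
                 folds=folds, seed=seed, engine=engine,
                 stem_pct_reading=stem_pct_reading)


def predict(model: TrainedModel, fm: FeatureMatrix):
    """Scores in [0, 1] and hard labels for a featurized matrix.

    The score is a fixed logistic map of the SVM margin; the label is
    score >= 0.5, equivalently a non-negative margin.
    """
    dv = model.decision_values(fm)
    scores = 1.0 / (1.0 + np.exp(-dv))
    labels = (scores >= 0.5).astype(int)
    return scores, labels


def predict_sequences(model: TrainedModel, items: list):
    """Fold-if-needed, featurize with the bundle's tables, and score.

    ``items`` may be Sequence objects or (Sequence, SecondaryStructure)
    pairs; bare sequences are folded with the model's engine.
    """
    pairs = []
    for it in items:
        if isinstance(it, tuple):
            pairs.append(it)
        else:
            pairs.append((it, fold(it, engine=model.engine)))
    fm = featurize_many(pairs, model.tables,
                        stem_pct_reading=model.stem_pct_reading)
    scores, labels = predict(model, fm)
    return fm.ids, scores, labels


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a model bundle directory (manifest sidecar + joblib state)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "manifest_version": model.manifest_version,
        "feature_names": list(FEATURE_NAMES),
        "C": model.C,
        "gamma": model.gamma,
        "seed": model.seed,
        "engine": model.engine,
        "stem_pct_reading": model.stem_pct_reading,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (path / "grid_record.json").write_text(json.dumps(model.grid_record, indent=2))
    joblib.dump(model, path / "model.joblib")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest["manifest_version"] != MANIFEST_VERSION:
        raise ConfigurationError(
            f"bundle manifest {manifest['manifest_version']!r} does not match "
            f"this package's {MANIFEST_VERSION!r}"
        )
    model = joblib.load(path / "model.joblib")
    return model
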