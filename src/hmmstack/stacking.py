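"""Two-stage stacked ensemble for binary protein classification.

Stage 1 trains a set of base classifiers (any of SVM with RBF kernel,
k-nearest neighbours, logistic regression, random forest, decision tree,
extreme gradient boosting) on the 420-dimensional AATP features.  Their
out-of-fold positive-class probabilities — each sample scored by learners
that never saw its fold — become the meta-feature matrix.  Stage 2 fits a
gradient-boosted decision tree (GBDT) meta-classifier on those
probabilities; at prediction time the refitted base learners feed the meta
learner, which emits the final positive-class probability.

Five named base-learner combinations are provided (SM1..SM5); SM1
(KNN + LR + DT + SVM-RBF) is the default predictor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .features import N_FEATURES, FeatureMatrix

__all__ = [
    "LEARNER_NAMES",
    "COMBINATIONS",
    "DEFAULT_GRIDS",
    "BaseLearnerSpec",
    "StackConfig",
    "StackedModel",
    "make_estimator",
    "tune_base_learner",
    "generate_meta_features",
    "train_stacked",
    "predict_proba",
    "predict",
    "save_model",
    "load_model",
]

LEARNER_NAMES = ("SVM_RBF", "KNN", "LR", "RF", "DT", "XGB")

#: Named base-learner combinations; SM1 is the default final predictor.
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "SM1": ("KNN", "LR", "DT", "SVM_RBF"),
    "SM2": ("KNN", "LR", "DT", "XGB"),
    "SM3": ("KNN", "LR", "DT", "RF"),
    "SM4": ("SVM_RBF", "XGB", "RF"),
    "SM5": ("KNN", "LR", "DT", "SVM_RBF", "RF", "XGB"),
}

#: Default grid-search spaces (fully overridable per call).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM_RBF": {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": list(np.logspace(-4, 0, 5)),
    },
    "KNN": {"n_neighbors": list(range(1, 32, 2))},
    "LR": {"C": [0.01, 0.1, 1.0, 10.0]},
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [3, 6, None]},
    "DT": {"max_depth": [3, 6, None]},
    "XGB": {"n_estimators": [100, 300, 500], "max_depth": [3, 6]},
}

_SCALED = {"SVM_RBF", "KNN", "LR"}  # learners that get the optional standardizer

MODEL_FORMAT_VERSION = 1


@dataclass
class BaseLearnerSpec:
    """One base classifier: its name and (possibly tuned) hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    tuned: bool = False

    def __post_init__(self):
        if self.name not in LEARNER_NAMES:
            raise ValueError(
                f"unknown base learner {self.name!r}; valid: {LEARNER_NAMES}"
            )


@dataclass
class StackConfig:
    """Configuration of a stacked model.

    ``combination`` names one of SM1..SM5 or ``"custom"`` (then
    ``base_specs`` must be given).  ``n_meta_folds`` controls the stratified
    out-of-fold construction of the meta-features; ``seed`` drives every
    randomized component; ``standardize`` wraps SVM/KNN/LR in a
    train-partition standardizer (tree learners always see raw features).
    """

    combination: str = "SM1"
    base_specs: Optional[list[BaseLearnerSpec]] = None
    meta: dict = field(default_factory=dict)
    n_meta_folds: int = 5
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.n_meta_folds < 2:
            raise ValueError("n_meta_folds must be >= 2")
        if self.base_specs is None:
            if self.combination not in COMBINATIONS:
                raise ValueError(
                    f"unknown combination {self.combination!r}; "
                    f"valid: {', '.join(COMBINATIONS)} or 'custom' with base_specs"
                )
            self.base_specs = [BaseLearnerSpec(n) for n in COMBINATIONS[self.combination]]
        if not self.base_specs:
            raise ValueError("base_specs must contain at least one learner")


@dataclass
class StackedModel:
    """A trained stack: refitted base learners plus the fitted meta-learner."""

    config: StackConfig
    fitted_base: list  # list of (name, fitted estimator)
    fitted_meta: GradientBoostingClassifier
    feature_layout: list[str]
    training_fingerprint: dict


def make_estimator(spec: BaseLearnerSpec, seed: int, standardize: bool):
    """Instantiate the scikit-learn / xgboost estimator for a spec."""
    hp = dict(spec.hyperparameters)
    if spec.name == "SVM_RBF":
        # sigmoid (Platt) calibration supplies class probabilities for SVC
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed, **hp),
            method="sigmoid",
            cv=3,
            ensemble=False,
        )
    elif spec.name == "KNN":
        est = KNeighborsClassifier(**hp)
    elif spec.name == "LR":
        est = LogisticRegression(max_iter=2000, random_state=seed, **hp)
    elif spec.name == "RF":
        est = RandomForestClassifier(random_state=seed, **hp)
    elif spec.name == "DT":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif spec.name == "XGB":
        est = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            **hp,
        )
    else:  # pragma: no cover - guarded by BaseLearnerSpec
        raise ValueError(spec.name)
    if standardize and spec.name in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _check_labeled(fm: FeatureMatrix) -> np.ndarray:
    if fm.y is None:
        raise ValueError("feature matrix must carry labels")
    y = fm.y
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all() or classes.size < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    return y


def _positive_proba(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    classes = est.named_steps["clf"].classes_ if isinstance(est, Pipeline) else est.classes_
    pos = int(np.flatnonzero(classes == 1)[0])
    return proba[:, pos]


def tune_base_learner(
    spec: BaseLearnerSpec,
    fm: FeatureMatrix,
    grid: Optional[dict[str, list]] = None,
    cv_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> BaseLearnerSpec:
    """Grid-search hyperparameters by mean stratified-CV accuracy.

    Candidates are enumerated in grid insertion order (itertools.product
    over the value lists); ties are broken in favour of the first candidate
    reaching the maximum.  Returns a new spec with ``tuned=True``.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[spec.name]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid is empty")
    y = _check_labeled(fm)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(fm.X, y))

    keys = list(grid.keys())
    best_params: Optional[dict] = None
    best_acc = -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = {**spec.hyperparameters, **dict(zip(keys, combo))}
        accs = []
        for tr, te in splits:
            est = make_estimator(replace(spec, hyperparameters=params), seed, standardize)
            est.fit(fm.X[tr], y[tr])
            accs.append(float(np.mean(est.predict(fm.X[te]) == y[te])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:  # strict: first-in-grid wins ties
            best_acc = mean_acc
            best_params = params
    assert best_params is not None
    return BaseLearnerSpec(name=spec.name, hyperparameters=best_params, tuned=True)


def generate_meta_features(
    base_specs: Sequence[BaseLearnerSpec],
    fm: FeatureMatrix,
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> FeatureMatrix:
    """Out-of-fold positive-class probabilities, one column per base learner.

    For each stratified fold, every base learner is trained on the other
    folds and scores the held-out fold; a sample's meta-features therefore
    never come from a learner trained on its own fold.  Row order matches
    the input matrix; a fixed seed makes the output reproducible.
    """
    if not base_specs:
        raise ValueError("base_specs must contain at least one learner")
    y = _check_labeled(fm)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into "
            f"{n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    Z = np.empty((len(fm), len(base_specs)), dtype=np.float64)
    for tr, te in skf.split(fm.X, y):
        for b, spec in enumerate(base_specs):
            est = make_estimator(spec, seed, standardize)
            est.fit(fm.X[tr], y[tr])
            Z[te, b] = _positive_proba(est, fm.X[te])
    return FeatureMatrix(
        ids=list(fm.ids), X=Z, y=y.copy(), names=[f"p_{s.name}" for s in base_specs]
    )


def train_stacked(config: StackConfig, fm: FeatureMatrix) -> StackedModel:
    """Train the two-stage stack on a labeled feature matrix.

    Builds out-of-fold meta-features, fits the GBDT meta-classifier on them,
    then refits every base learner on the full training data.  Constant
    meta-feature columns are permitted but flagged in the fingerprint.
    """
    y = _check_labeled(fm)
    if fm.X.shape[1] != N_FEATURES:
        raise ValueError(
            f"expected {N_FEATURES} feature columns, got {fm.X.shape[1]}"
        )
    meta_fm = generate_meta_features(
        config.base_specs, fm, config.n_meta_folds, config.seed, config.standardize
    )
    meta_params = {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3}
    meta_params.update(config.meta)
    meta = GradientBoostingClassifier(random_state=config.seed, **meta_params)
    meta.fit(meta_fm.X, y)

    fitted_base = []
    for spec in config.base_specs:
        est = make_estimator(spec, config.seed, config.standardize)
        est.fit(fm.X, y)
        fitted_base.append((spec.name, est))

    degenerate = [
        config.base_specs[b].name
        for b in range(meta_fm.X.shape[1])
        if np.ptp(meta_fm.X[:, b]) == 0.0
    ]
    fingerprint = {
        "n": int(len(fm)),
        "n_positive": int(y.sum()),
        "n_negative": int(len(y) - y.sum()),
        "seed": int(config.seed),
        "training_ids": list(fm.ids),
        "degenerate_meta_columns": degenerate,
    }
    return StackedModel(
        config=config,
        fitted_base=fitted_base,
        fitted_meta=meta,
        feature_layout=list(fm.names),
        training_fingerprint=fingerprint,
    )


def _check_layout(model: StackedModel, fm: FeatureMatrix) -> None:
    if fm.X.shape[1] != len(model.feature_layout):
        raise ValueError(
            f"feature count mismatch: model expects {len(model.feature_layout)} "
            f"columns, input has {fm.X.shape[1]}"
        )
    if fm.names != model.feature_layout:
        diff = [
            (a, b) for a, b in zip(fm.names, model.feature_layout) if a != b
        ][:5]
        if diff:
            raise ValueError(f"feature name mismatch (first differences: {diff})")


def predict_proba(model: StackedModel, fm: FeatureMatrix) -> np.ndarray:
    """Final positive-class probability for every row of ``fm``."""
    _check_layout(model, fm)
    Z = np.column_stack(
        [_positive_proba(est, fm.X) for _, est in model.fitted_base]
    )
    classes = model.fitted_meta.classes_
    pos = int(np.flatnonzero(classes == 1)[0])
    return model.fitted_meta.predict_proba(Z)[:, pos]


def predict(
    model: StackedModel, fm: FeatureMatrix, threshold: float = 0.5
) -> np.ndarray:
    """Hard labels: 1 iff the stacked probability is >= ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (predict_proba(model, fm) >= threshold).astype(np.int64)


def save_model(model: StackedModel, path: Union[str, Path]) -> None:
    """Serialize a trained stack (config, learners, layout, format version)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: Union[str, Path]) -> StackedModel:
    """Load a model saved by :func:`save_model`; validates the format version."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an hmmstack model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
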