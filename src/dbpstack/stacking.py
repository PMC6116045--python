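"""Stacked generalization over per-feature-space base classifiers.

Base classifiers (RBF SVM, random forest, Gaussian naive Bayes) are fit
independently on each of the four feature spaces; their positive-class
probabilities become the meta-features f_1..f_N of a logistic-regression
combiner

    P(y = 1 | f) = 1 / (1 + exp(-(theta_0 + theta_1 f_1 + ... + theta_N f_N)))

whose coefficients are estimated by maximum likelihood (a tiny ridge of
1e-6 on the slopes, none on the intercept, guarantees convergence under
perfect separation). Meta-training uses out-of-fold base probabilities by
default (stratified k-fold) so the combiner never sees in-sample
optimism; an in-sample mode exists for comparison.

The three predictor families — {svm}, {svm, rf}, {svm, rf, nb} — over the
four feature blocks yield N = 4, 8 and 12 base models respectively.
"""

from __future__ import annotations

import json
import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import SchemaError

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("svm_rbf", "random_forest", "gaussian_nb")
BLOCK_NAMES = ("local_dpp", "pssm_dwt", "d188", "ac_struct")

#: Predictor families, keyed by the short names used on the command line.
FAMILIES = {
    "svm": ("svm_rbf",),
    "svm,rf": ("svm_rbf", "random_forest"),
    "svm,rf,nb": ("svm_rbf", "random_forest", "gaussian_nb"),
}

#: Meta-learner ridge strength on the slopes (1/C for the LBFGS solver).
META_RIDGE = 1e-6


@contextmanager
def _quiet_fit():
    # scikit-learn 1.9 deprecates SVC(probability=True); Platt-scaled
    # probabilities are part of this model's contract, so keep it quiet.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*probability.*", category=FutureWarning
        )
        yield


def default_grid(classifier_kind: str) -> dict:
    """Full hyperparameter search grids (grid search by 5-fold CV accuracy)."""
    if classifier_kind == "svm_rbf":
        return {
            "C": [2.0**e for e in range(-5, 16, 2)],
            "gamma": [2.0**e for e in range(-15, 4, 2)],
        }
    if classifier_kind == "random_forest":
        return {
            "n_estimators": [100, 300, 500],
            "max_features": ["sqrt", "log2"],
            "min_samples_leaf": [1, 3, 5],
        }
    if classifier_kind == "gaussian_nb":
        return {}
    raise ValueError(f"unknown classifier kind {classifier_kind!r}")


def small_grid(classifier_kind: str) -> dict:
    """Reduced grids for quick, desk-scale runs."""
    if classifier_kind == "svm_rbf":
        return {"C": [1.0, 32.0], "gamma": ["scale"]}
    if classifier_kind == "random_forest":
        return {"n_estimators": [100], "max_features": ["sqrt"], "min_samples_leaf": [1]}
    if classifier_kind == "gaussian_nb":
        return {}
    raise ValueError(f"unknown classifier kind {classifier_kind!r}")


@dataclass(frozen=True)
class BaseModelSpec:
    """One (classifier kind, feature block) base model with its search grid."""

    classifier_kind: str
    feature_block: str
    hyperparameter_grid: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.classifier_kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.classifier_kind!r}")

    @property
    def grid(self) -> dict:
        if self.hyperparameter_grid is None:
            return default_grid(self.classifier_kind)
        return self.hyperparameter_grid

    @property
    def name(self) -> str:
        return f"{self.classifier_kind}:{self.feature_block}"


def specs_for_family(
    family: Sequence[str] | str,
    blocks: Sequence[str] = BLOCK_NAMES,
    grids: Optional[Mapping[str, dict]] = None,
) -> list[BaseModelSpec]:
    """Base-model specs in classifier-major order over the feature blocks."""
    if isinstance(family, str):
        family = FAMILIES[family]
    specs = []
    for kind in family:
        grid = grids.get(kind) if grids is not None else None
        for block in blocks:
            specs.append(BaseModelSpec(kind, block, grid))
    return specs


def _make_estimator(kind: str, params: Mapping, seed: int) -> Pipeline:
    """Estimator pipeline; features are standardized before the SVM and the
    Gaussian NB, the random forest is left unscaled."""
    if kind == "svm_rbf":
        steps = [
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", probability=True, random_state=seed)),
        ]
    elif kind == "random_forest":
        steps = [("clf", RandomForestClassifier(random_state=seed, n_jobs=1))]
    elif kind == "gaussian_nb":
        steps = [("scale", StandardScaler()), ("clf", GaussianNB())]
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    pipe = Pipeline(steps)
    if params:
        pipe.set_params(**{f"clf__{k}": v for k, v in params.items()})
    return pipe


@dataclass(eq=False)
class FittedBase:
    """A fitted base model plus the grid point selected for it."""

    spec: BaseModelSpec
    estimator: Pipeline
    chosen_params: dict

    def positive_proba(self, x: np.ndarray) -> np.ndarray:
        clf = self.estimator
        idx = list(clf.classes_).index(1)
        return clf.predict_proba(x)[:, idx]


def _check_two_classes(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")


def fit_base(spec: BaseModelSpec, x, y, seed: int) -> FittedBase:
    """Fit one base model, selecting its grid point by internal stratified
    5-fold CV accuracy (skipped when the grid has at most one point)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    grid = spec.grid
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    if n_points <= 1:
        params = {k: v[0] for k, v in grid.items()}
        estimator = _make_estimator(spec.classifier_kind, params, seed)
        with _quiet_fit():
            estimator.fit(x, y)
        return FittedBase(spec, estimator, dict(params))
    min_count = int(np.unique(y, return_counts=True)[1].min())
    cv = StratifiedKFold(
        n_splits=max(2, min(5, min_count)), shuffle=True, random_state=seed
    )
    search = GridSearchCV(
        _make_estimator(spec.classifier_kind, {}, seed),
        {f"clf__{k}": v for k, v in grid.items()},
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    with _quiet_fit():
        search.fit(x, y)
    chosen = {k[len("clf__") :]: v for k, v in search.best_params_.items()}
    return FittedBase(spec, search.best_estimator_, chosen)


@dataclass(eq=False)
class MetaFeatureMatrix:
    """Samples x N out-of-fold positive-class probabilities with labels."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("meta-features must be probabilities in [0, 1]")


def _splits(y: np.ndarray, k: int, seed: int):
    if k == y.size:
        return list(LeaveOneOut().split(np.zeros((y.size, 1)), y))
    return list(
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(
            np.zeros((y.size, 1)), y
        )
    )


def oof_meta_features(
    specs: Sequence[BaseModelSpec],
    blocks: Mapping[str, np.ndarray],
    y,
    k: int = 5,
    seed: int = 0,
    chosen_params: Optional[Mapping[str, dict]] = None,
) -> MetaFeatureMatrix:
    """Out-of-fold positive-class probabilities for every (sample, spec) pair.

    When ``chosen_params`` maps spec names to grid points, fold models reuse
    those hyperparameters (the fast, frozen-grid mode); otherwise each fold
    reruns the full grid search.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("fold count k must be >= 2")
    for attempt in range(5):
        splits = _splits(y, k, seed + 1000 * attempt)
        if all(np.unique(y[train]).size == 2 for train, _ in splits):
            break
        logger.warning("fold with a single class; reseeding split (attempt %d)", attempt + 1)
    else:
        raise ValueError("could not stratify labels into %d folds" % k)
    values = np.full((y.size, len(specs)), np.nan)
    for train, test in splits:
        for j, spec in enumerate(specs):
            x = np.asarray(blocks[spec.feature_block], dtype=float)
            if chosen_params is not None and spec.name in chosen_params:
                est = _make_estimator(
                    spec.classifier_kind, chosen_params[spec.name], seed
                )
                with _quiet_fit():
                    est.fit(x[train], y[train])
                fitted = FittedBase(spec, est, dict(chosen_params[spec.name]))
            else:
                fitted = fit_base(spec, x[train], y[train], seed)
            values[test, j] = fitted.positive_proba(x[test])
    return MetaFeatureMatrix(values, y)


def fit_meta(mf: MetaFeatureMatrix) -> np.ndarray:
    """Maximum-likelihood logistic coefficients theta_0..theta_N.

    A ridge of ``META_RIDGE`` on the slopes (never the intercept) keeps the
    optimum finite under perfect separation, in which case a warning is
    logged.
    """
    _check_two_classes(mf.labels)
    lr = LogisticRegression(
        C=1.0 / META_RIDGE, solver="lbfgs", max_iter=10000, tol=1e-8
    )
    lr.fit(mf.values, mf.labels)
    theta = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    preds = (mf.values @ theta[1:] + theta[0]) >= 0
    if np.array_equal(preds.astype(int), mf.labels):
        logger.warning(
            "meta-features perfectly separate the classes; coefficients are "
            "ridge-stabilized (ridge=%g)",
            META_RIDGE,
        )
    return theta


@dataclass(eq=False)
class StackedModel:
    """Fitted base models plus logistic meta-coefficients."""

    base_models: list[FittedBase]
    theta: np.ndarray
    meta_feature_order: list[tuple[str, str]]
    metadata: dict = field(default_factory=dict)

    @property
    def n_meta_features(self) -> int:
        return len(self.base_models)


def fit_stacked(
    blocks: Mapping[str, np.ndarray],
    y,
    specs: Sequence[BaseModelSpec],
    k: int = 5,
    seed: int = 0,
    oof: bool = True,
    freeze_grids: bool = True,
    metadata: Optional[dict] = None,
) -> StackedModel:
    """Train the full stack: base models on all data, meta-learner on their
    (by default out-of-fold) probabilities."""
    y = np.asarray(y, dtype=int)
    fitted = [fit_base(spec, blocks[spec.feature_block], y, seed) for spec in specs]
    chosen = {fb.spec.name: fb.chosen_params for fb in fitted}
    if oof:
        mf = oof_meta_features(
            specs, blocks, y, k=k, seed=seed,
            chosen_params=chosen if freeze_grids else None,
        )
    else:
        mf = MetaFeatureMatrix(
            np.column_stack(
                [fb.positive_proba(np.asarray(blocks[fb.spec.feature_block], float))
                 for fb in fitted]
            ),
            y,
        )
    theta = fit_meta(mf)
    meta = {
        "seed": seed,
        "k": k,
        "oof": oof,
        "freeze_grids": freeze_grids,
        "meta_ridge": META_RIDGE,
        "chosen_params": chosen,
    }
    if metadata:
        meta.update(metadata)
    return StackedModel(
        base_models=fitted,
        theta=theta,
        meta_feature_order=[(s.classifier_kind, s.feature_block) for s in specs],
        metadata=meta,
    )


def _meta_features(model: StackedModel, blocks: Mapping[str, np.ndarray]) -> np.ndarray:
    cols = []
    for fb in model.base_models:
        block = fb.spec.feature_block
        if block not in blocks:
            raise SchemaError(f"missing feature block {block!r}")
        x = np.asarray(blocks[block], dtype=float)
        expected = fb.estimator.named_steps["clf"].n_features_in_
        if x.shape[1] != expected:
            raise SchemaError(
                f"block {block!r}: {x.shape[1]} features but the model was "
                f"trained with {expected}"
            )
        cols.append(fb.positive_proba(x))
    return np.column_stack(cols)


def predict(model: StackedModel, blocks: Mapping[str, np.ndarray]):
    """Stacked probabilities and labels; probability ties at 0.5 go positive."""
    f = _meta_features(model, blocks)
    z = model.theta[0] + f @ model.theta[1:]
    proba = 1.0 / (1.0 + np.exp(-z))
    return proba, (proba >= 0.5).astype(int)


def majority_vote(
    fitted_singles: Sequence[FittedBase], blocks: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Majority vote over fitted base models.

    The label with strictly more votes wins; exact ties are broken by the
    mean positive-class probability (>= 0.5 goes positive).
    """
    if not fitted_singles:
        raise ValueError("need at least one voter")
    probas = np.column_stack(
        [
            fb.positive_proba(np.asarray(blocks[fb.spec.feature_block], float))
            for fb in fitted_singles
        ]
    )
    votes = (probas >= 0.5).sum(axis=1)
    n = probas.shape[1]
    labels = np.where(votes * 2 > n, 1, 0)
    tie = votes * 2 == n
    labels[tie] = (probas[tie].mean(axis=1) >= 0.5).astype(int)
    return labels


def save_model(model: StackedModel, directory) -> None:
    """Persist a stacked model as JSON metadata plus joblib estimators."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "theta": [float(v) for v in model.theta],
        "meta_feature_order": [list(pair) for pair in model.meta_feature_order],
        "metadata": model.metadata,
        "specs": [
            {
                "classifier_kind": fb.spec.classifier_kind,
                "feature_block": fb.spec.feature_block,
                "chosen_params": fb.chosen_params,
            }
            for fb in model.base_models
        ],
    }
    (directory / "metadata.json").write_text(
        json.dumps(meta, indent=2, default=str), encoding="utf-8"
    )
    for i, fb in enumerate(model.base_models):
        joblib.dump(fb.estimator, directory / f"base_{i:02d}.joblib")


def load_model(directory) -> StackedModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text(encoding="utf-8"))
    base_models = []
    for i, spec_meta in enumerate(meta["specs"]):
        estimator = joblib.load(directory / f"base_{i:02d}.joblib")
        spec = BaseModelSpec(
            spec_meta["classifier_kind"], spec_meta["feature_block"]
        )
        base_models.append(FittedBase(spec, estimator, spec_meta["chosen_params"]))
    return StackedModel(
        base_models=base_models,
        theta=np.array(meta["theta"], dtype=float),
        meta_feature_order=[tuple(p) for p in meta["meta_feature_order"]],
        metadata=meta["metadata"],
    )
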