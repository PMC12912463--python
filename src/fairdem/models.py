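"""Four classifier families with the audit's split and tuning protocol.

The protocol: a stratified, seeded 70/30 train/test split; per family,
hyperparameters chosen by 5-fold cross-validation on the training partition
maximizing balanced accuracy (= 1 - balanced error rate, aligning tuning
with the audit metric); final refit on the full training partition; hard
labels at the 0.5 probability threshold (decision-function sign for the
margin classifier).  Continuous features are z-scored inside the estimator
pipeline for the scale-sensitive families (logistic regression, SVM,
Gaussian naive Bayes) and left raw for the forest; standardization
parameters are therefore fit on training rows only by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .config import SplitConfig

FAMILIES = ("random_forest", "logistic_regression", "svm", "naive_bayes")


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def n_grid_points(self) -> int:
        n = 1
        for v in self.grid.values():
            n *= len(v)
        return n


def default_specs() -> dict[str, ModelSpec]:
    """Desk-scale CV grids for the four families."""
    return {
        "random_forest": ModelSpec(
            "random_forest",
            {"clf__n_estimators": [200, 500], "clf__max_depth": [None, 10]},
            standardize=False,
        ),
        "logistic_regression": ModelSpec(
            "logistic_regression",
            {"clf__C": list(np.logspace(-2, 2, 5))},
        ),
        "svm": ModelSpec(
            "svm",
            {"clf__C": list(np.logspace(-1.5, 1.5, 4)), "clf__gamma": ["scale"]},
        ),
        "naive_bayes": ModelSpec(
            "naive_bayes",
            {"clf__var_smoothing": [1e-9, 1e-7, 1e-5]},
        ),
    }


def fast_specs() -> dict[str, ModelSpec]:
    """Single-point grids (no CV search) for large simulation sweeps."""
    return {
        "random_forest": ModelSpec(
            "random_forest",
            {"clf__n_estimators": [200], "clf__max_depth": [None]},
            standardize=False,
        ),
        "logistic_regression": ModelSpec("logistic_regression", {"clf__C": [1.0]}),
        "svm": ModelSpec("svm", {"clf__C": [1.0], "clf__gamma": ["scale"]}),
        "naive_bayes": ModelSpec("naive_bayes", {"clf__var_smoothing": [1e-9]}),
    }


def split_data(
    X: pd.DataFrame, y, cfg: SplitConfig
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Seeded, stratified, disjoint and exhaustive train/test partition."""
    if len(X) == 0:
        raise ValueError("cannot split an empty feature matrix")
    y = np.asarray(y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=cfg.train_fraction,
        stratify=y,
        random_state=cfg.seed,
        shuffle=True,
    )
    for part, name in ((y_tr, "train"), (y_te, "test")):
        if len(np.unique(part)) < 2:
            raise ValueError(
                f"{name} partition lost an outcome class; use a larger fixture"
            )
    return X_tr, X_te, y_tr, y_te


def _base_estimator(spec: ModelSpec, continuous_columns: list[str], seed: int) -> Pipeline:
    if spec.family == "random_forest":
        clf = RandomForestClassifier(random_state=seed, n_jobs=1)
    elif spec.family == "logistic_regression":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif spec.family == "svm":
        clf = SVC(kernel="rbf", random_state=seed)
    else:
        clf = GaussianNB()
    steps = []
    if spec.standardize:
        # z-score continuous columns only; nominal flags pass through
        pre = ColumnTransformer(
            [("scale", StandardScaler(), continuous_columns)],
            remainder="passthrough",
            verbose_feature_names_out=False,
        )
        steps.append(("pre", pre))
    steps.append(("clf", clf))
    return Pipeline(steps)


class DementiaRiskClassifier(BaseEstimator, ClassifierMixin):
    """One family of the model zoo as a scikit-learn estimator.

    Parameters
    ----------
    family : one of ``FAMILIES``.
    spec : optional explicit :class:`ModelSpec`; defaults to the family's
        entry in :func:`default_specs`.
    continuous_columns : columns to z-score for scale-sensitive families
        (defaults to all columns).
    cv_folds, seed : cross-validation protocol; with a single grid point the
        search is skipped and that point is used directly.
    """

    def __init__(
        self,
        family: str = "logistic_regression",
        spec: ModelSpec | None = None,
        continuous_columns: list[str] | None = None,
        cv_folds: int = 5,
        seed: int = 0,
    ) -> None:
        self.family = family
        self.spec = spec
        self.continuous_columns = continuous_columns
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "DementiaRiskClassifier":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both outcome classes")
        spec = self.spec or default_specs()[self.family]
        cont = (
            list(X.columns)
            if self.continuous_columns is None
            else list(self.continuous_columns)
        )
        base = _base_estimator(spec, cont, self.seed)
        if spec.n_grid_points == 1:
            params = {k: v[0] for k, v in spec.grid.items()}
            est = clone(base).set_params(**params)
            est.fit(X, y)
            self.best_params_ = params
            self.cv_results_ = None
        else:
            cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
            search = GridSearchCV(
                base,
                spec.grid,
                scoring="balanced_accuracy",
                cv=cv,
                n_jobs=1,
                refit=True,
            )
            search.fit(X, y)
            est = search.best_estimator_
            self.best_params_ = search.best_params_
            self.cv_results_ = {
                "mean_test_score": search.cv_results_["mean_test_score"].tolist(),
                "params": [str(p) for p in search.cv_results_["params"]],
            }
        self.estimator_ = est
        self.classes_ = np.unique(y)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("feature columns do not match the fitted manifest")
        if len(X) == 0:
            return np.array([], dtype=self.classes_.dtype)
        return self.estimator_.predict(X)


def tune_and_fit(
    X_train: pd.DataFrame,
    y_train,
    spec: ModelSpec,
    cfg: SplitConfig,
    continuous_columns: list[str] | None = None,
) -> DementiaRiskClassifier:
    """Grid search (balanced accuracy, stratified K-fold) + refit on the full
    training partition; returns the fitted estimator with ``best_params_``."""
    model = DementiaRiskClassifier(
        family=spec.family,
        spec=spec,
        continuous_columns=continuous_columns,
        cv_folds=cfg.cv_folds,
        seed=cfg.seed,
    )
    return model.fit(X_train, y_train)


def predict_labels(model: DementiaRiskClassifier, X_test: pd.DataFrame) -> np.ndarray:
    """One hard label per row (0.5 probability threshold / decision sign)."""
    return model.predict(X_test)
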