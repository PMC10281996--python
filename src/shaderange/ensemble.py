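"""Four-algorithm consensus species distribution model.

Per species, four presence/pseudo-absence classifiers — GLM (logistic
regression with linear + quadratic terms), GAM (additive cubic-spline
logistic model), GBM (gradient-boosted trees) and RF (random forest) — are
evaluated by stratified fourfold cross-validation (AUC and TSS on each held
out fold), then refitted on all the data and combined as a weighted average
of their suitability scores. Weights derive from mean cross-validated AUC:
by default ``max(AUC - 0.5, 0)`` renormalized, so an algorithm at or below
chance contributes nothing; a ``raw`` mode weights by AUC itself. The
ensemble's binarization threshold maximizes sensitivity + specificity on the
full training data.

Per-species variable importance is permutation importance under the best
(highest mean CV AUC) algorithm: mean AUC drop when a predictor is shuffled,
negatives truncated to zero, rescaled to sum 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, SplineTransformer, StandardScaler

from .grids import CLIMATIC, EDAPHIC
from .metrics import auc, optimize_threshold

ALGORITHMS = ("GLM", "GAM", "GBM", "RF")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "GLM": {},
    "GAM": {"n_knots": 5, "degree": 3},
    "GBM": {"n_estimators": 2000, "learning_rate": 0.01, "max_depth": 3},
    "RF": {"n_estimators": 500},
}


def _append_squares(X):
    return np.hstack([X, np.asarray(X) ** 2])


@dataclass
class TrainingSet:
    """Labelled presence/pseudo-absence rows with predictors and CV folds."""

    species_id: str
    X: pd.DataFrame
    y: np.ndarray  # 1 = presence, 0 = pseudo-absence
    folds: np.ndarray  # 1..k
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).astype(int)
        self.folds = np.asarray(self.folds).astype(int)
        if not (len(self.X) == len(self.y) == len(self.folds)):
            raise ValueError("X, y and folds must have equal length")
        if self.y.min() == self.y.max():
            raise ValueError("both presences and pseudo-absences required")
        if self.X.isna().any().any():
            raise ValueError("predictor matrix contains missing values")

    @property
    def predictors(self) -> list[str]:
        return list(self.X.columns)

    @property
    def k(self) -> int:
        return int(self.folds.max())


def assign_folds(y, k: int = 4, seed: int = 0) -> np.ndarray:
    """Random fold labels 1..k stratified by class.

    Within each class the shuffled indices are split as evenly as possible
    (sizes differ by at most 1), so no fold can end up single-class.
    """
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    folds = np.zeros(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} points, fewer than k={k}")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k), start=1):
            folds[chunk] = f
    return folds


class Learner:
    """One fitted algorithm exposing a suitability score in [0, 1]."""

    def __init__(self, algorithm: str, seed: int = 0, hyperparams: dict | None = None):
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
        self.algorithm = algorithm
        self.seed = seed
        hp = dict(DEFAULT_HYPERPARAMS[algorithm])
        hp.update(hyperparams or {})
        self.hyperparams = hp
        self._model = self._build()
        self._fitted = False

    def _build(self):
        hp = self.hyperparams
        if self.algorithm == "GLM":
            return Pipeline([
                ("quad", FunctionTransformer(_append_squares)),
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(C=100.0, max_iter=5000)),
            ])
        if self.algorithm == "GAM":
            return Pipeline([
                ("spline", SplineTransformer(n_knots=hp["n_knots"], degree=hp["degree"],
                                             extrapolation="constant")),
                ("lr", LogisticRegression(C=1.0, max_iter=5000)),
            ])
        if self.algorithm == "GBM":
            return GradientBoostingClassifier(
                n_estimators=hp["n_estimators"], learning_rate=hp["learning_rate"],
                max_depth=hp["max_depth"], random_state=self.seed)
        return RandomForestClassifier(n_estimators=hp["n_estimators"],
                                      random_state=self.seed, n_jobs=1)

    def fit(self, X, y) -> "Learner":
        y = np.asarray(y).astype(int)
        if y.min() == y.max():
            raise ValueError("cannot fit on single-class data")
        self._model.fit(np.asarray(X, dtype=float), y)
        self._fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("learner not fitted")
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def fit_learner(algorithm: str, X, y, seed: int = 0,
                hyperparams: dict | None = None) -> Learner:
    return Learner(algorithm, seed=seed, hyperparams=hyperparams).fit(X, y)


def cross_validate(training: TrainingSet,
                   algorithms: tuple[str, ...] = ALGORITHMS,
                   seed: int = 0,
                   hyperparams: dict[str, dict] | None = None) -> pd.DataFrame:
    """Per-algorithm, per-fold held-out AUC and TSS.

    TSS is evaluated at the held-out fold's own optimal threshold. A fold
    whose held-out part is single-class yields NaN metrics (excluded from
    means downstream).
    """
    hp = hyperparams or {}
    rows = []
    X = training.X.to_numpy(dtype=float)
    for algo in algorithms:
        for f in range(1, training.k + 1):
            test = training.folds == f
            train = ~test
            if training.y[test].min() == training.y[test].max():
                warnings.warn(f"fold {f} held-out part is single-class; metrics NaN",
                              stacklevel=2)
                rows.append({"algorithm": algo, "fold": f,
                             "auc": np.nan, "tss": np.nan, "threshold": np.nan})
                continue
            learner = fit_learner(algo, X[train], training.y[train],
                                  seed=seed, hyperparams=hp.get(algo))
            scores = learner.predict(X[test])
            tm = optimize_threshold(scores, training.y[test])
            rows.append({"algorithm": algo, "fold": f,
                         "auc": auc(scores, training.y[test]),
                         "tss": tm.tss, "threshold": tm.threshold})
    return pd.DataFrame(rows)


def mean_cv_auc(cv_metrics: pd.DataFrame) -> dict[str, float]:
    return cv_metrics.groupby("algorithm")["auc"].mean().to_dict()


def compute_weights(mean_aucs: dict[str, float], mode: str = "skill") -> dict[str, float]:
    """Ensemble weights from mean cross-validated AUC.

    ``skill`` (default): weight = max(AUC - 0.5, 0), renormalized; models at
    or below chance get zero. ``raw``: weight = AUC, renormalized (the
    literal weighted-average-by-AUC reading).
    """
    if mode not in ("skill", "raw"):
        raise ValueError("mode must be 'skill' or 'raw'")
    if mode == "raw":
        total = sum(mean_aucs.values())
        return {a: v / total for a, v in mean_aucs.items()}
    w = {a: max(v - 0.5, 0.0) for a, v in mean_aucs.items()}
    total = sum(w.values())
    if total <= 0:
        raise ValueError("no skillful model: all mean AUCs <= 0.5")
    return {a: v / total for a, v in w.items()}


@dataclass
class EnsembleModel:
    """AUC-weighted consensus of refitted learners, with its binarization
    threshold."""

    species_id: str
    learners: dict[str, Learner]
    weights: dict[str, float]
    threshold: float
    predictors: list[str]
    cv_metrics: pd.DataFrame
    ensemble_auc: float
    ensemble_tss: float

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def predict(self, X) -> np.ndarray:
        """Weighted-average suitability in [0, 1] for predictor rows."""
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for algo, w in self.weights.items():
            if w > 0:
                out += w * self.learners[algo].predict(X)
        return out

    @property
    def best_algorithm(self) -> str:
        means = mean_cv_auc(self.cv_metrics)
        return max(means, key=lambda a: means[a])


def fit_ensemble(training: TrainingSet, weights: dict[str, float] | None = None,
                 algorithms: tuple[str, ...] = ALGORITHMS, seed: int = 0,
                 hyperparams: dict[str, dict] | None = None,
                 weight_mode: str = "skill",
                 cv_metrics: pd.DataFrame | None = None) -> EnsembleModel:
    """Cross-validate (unless metrics given), weight, refit on all data and
    set the ensemble threshold."""
    hp = hyperparams or {}
    if cv_metrics is None:
        cv_metrics = cross_validate(training, algorithms=algorithms, seed=seed,
                                    hyperparams=hp)
    if weights is None:
        weights = compute_weights(mean_cv_auc(cv_metrics), mode=weight_mode)
    X = training.X.to_numpy(dtype=float)
    learners = {
        algo: fit_learner(algo, X, training.y, seed=seed, hyperparams=hp.get(algo))
        for algo in algorithms
    }
    model = EnsembleModel(species_id=training.species_id, learners=learners,
                          weights=weights, threshold=0.5,
                          predictors=training.predictors, cv_metrics=cv_metrics,
                          ensemble_auc=np.nan, ensemble_tss=np.nan)
    scores = model.predict(X)
    tm = optimize_threshold(scores, training.y)
    model.threshold = tm.threshold
    model.ensemble_auc = auc(scores, training.y)
    model.ensemble_tss = tm.tss
    return model


@dataclass
class VariableImportance:
    """Permutation importance (%) under the species' best algorithm."""

    species_id: str
    best_algorithm: str
    importance: pd.Series  # name -> percent, sums to 100
    class_sums: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = float(self.importance.sum())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"importances must sum to 100, got {total}")


def variable_importance(model: EnsembleModel, training: TrainingSet,
                        n_permutations: int = 5, seed: int = 0,
                        variable_class: dict[str, str] | None = None
                        ) -> VariableImportance:
    """AUC-drop permutation importance on the best algorithm.

    Each predictor column is shuffled ``n_permutations`` times; the mean drop
    in training AUC (negatives truncated to 0) is rescaled to sum 100.
    """
    best = model.best_algorithm
    learner = model.learners[best]
    X = training.X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base = auc(learner.predict(X), training.y)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j] += base - auc(learner.predict(Xp), training.y)
    drops = np.maximum(drops / n_permutations, 0.0)
    if drops.sum() <= 0:
        warnings.warn("no predictor showed positive permutation importance; "
                      "reporting a uniform split", stacklevel=2)
        pct = np.full(X.shape[1], 100.0 / X.shape[1])
    else:
        pct = 100.0 * drops / drops.sum()
    imp = pd.Series(pct, index=training.predictors)
    class_sums: dict[str, float] = {}
    if variable_class is not None:
        unknown = [n for n in training.predictors if n not in variable_class]
        if unknown:
            raise ValueError(f"variable_class missing predictors: {unknown}")
        for cls in (CLIMATIC, EDAPHIC):
            names = [n for n in training.predictors if variable_class[n] == cls]
            class_sums[cls] = float(imp[names].sum())
    return VariableImportance(species_id=model.species_id, best_algorithm=best,
                              importance=imp, class_sums=class_sums)
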