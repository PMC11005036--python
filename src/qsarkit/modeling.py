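"""Model training: bounded random search over gradient-boosted tree
learners, pooled 10-fold cross-validation, and a greedy forward-selection
ensemble of the best candidates.

The search emulates an AutoML workflow at a configurable budget: each
candidate is an XGBoost or LightGBM learner with randomized
hyperparameters, scored by its pooled out-of-fold performance (RMSE for
regression, log loss for classification) under a shared fold assignment.
A Caruana-style forward-selection ensemble (selection with replacement,
so members acquire integer weights) is then grown on the out-of-fold
predictions; the single best candidate is the degenerate one-member
case.  Everything stochastic — fold shuffling, hyperparameter sampling,
learner seeds — derives from one master seed recorded in the bundle.

Classification ensembles combine *raw margins* (log-odds) rather than
probabilities: the weighted-mean margin passes through one sigmoid.
This keeps the ensemble an additive model of its members, so exact
TreeSHAP attributions of the members combine linearly into attributions
for the ensemble (see the applicability-domain module).
"""

from __future__ import annotations

import time
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import lightgbm as lgb
import numpy as np
import pandas as pd
import xgboost as xgb

from .descriptors import DescriptorMatrix, FeatureFilterReport
from .metrics import ConfusionMatrix, CVMetrics, EvalPairs, classification_metrics, r_squared, rmse

REGRESSION = "regression"
CLASSIFICATION = "classification"

#: Hard cap on forward-selection picks (with replacement).
MAX_ENSEMBLE_PICKS = 10


class ModelingError(ValueError):
    pass


@dataclass
class TrainingConfig:
    task: str = REGRESSION
    n_folds: int = 10
    search_budget: int = 32
    seed: int = 0
    time_limit: Optional[float] = None  # seconds; None = unbounded

    def __post_init__(self) -> None:
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ModelingError(f"unknown task {self.task!r}")
        if self.n_folds < 2:
            raise ModelingError("n_folds must be at least 2")
        if self.search_budget < 1:
            raise ModelingError("search budget must be at least 1")


def make_folds(n_records: int, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each record to one validation fold.

    Fold sizes differ by at most one; the assignment is a seeded
    permutation, identical across runs with the same seed.
    """
    if n_records < n_folds:
        raise ModelingError(
            f"cannot make {n_folds} folds from {n_records} records"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    assignment = np.empty(n_records, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        assignment[chunk] = fold
    return assignment


# ---------------------------------------------------------------------------
# Learner adapters — a uniform fit / margin / TreeSHAP interface
# ---------------------------------------------------------------------------

class _BaseLearner:
    """One gradient-boosted candidate with fixed hyperparameters."""

    family = "base"

    def __init__(self, params: Dict, task: str, seed: int):
        self.params = dict(params)
        self.task = task
        self.seed = int(seed)
        self.model = None

    def clone(self) -> "_BaseLearner":
        return type(self)(self.params, self.task, self.seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseLearner":
        raise NotImplementedError

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        """Raw model output: the prediction for regression, log-odds for
        classification."""
        raise NotImplementedError

    def shap_contributions(self, X: np.ndarray) -> np.ndarray:
        """Exact TreeSHAP contributions, shape (n, p+1); the last column
        is the expected value (bias), so rows sum to the margin."""
        raise NotImplementedError


class XGBLearner(_BaseLearner):
    family = "Xgboost"

    def fit(self, X, y):
        cls = xgb.XGBRegressor if self.task == REGRESSION else xgb.XGBClassifier
        self.model = cls(
            **self.params,
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        self.model.fit(np.asarray(X, dtype=np.float32), y)
        return self

    def predict_margin(self, X):
        X = np.asarray(X, dtype=np.float32)
        if self.task == REGRESSION:
            return self.model.predict(X).astype(np.float64)
        return self.model.predict(X, output_margin=True).astype(np.float64)

    def shap_contributions(self, X):
        dmat = xgb.DMatrix(np.asarray(X, dtype=np.float32))
        return self.model.get_booster().predict(dmat, pred_contribs=True).astype(np.float64)


@contextmanager
def _quiet_feature_names():
    # LightGBM's sklearn wrapper warns on every ndarray predict call;
    # all our matrices carry their column order explicitly.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        yield


class LGBLearner(_BaseLearner):
    family = "LightGBM"

    def fit(self, X, y):
        cls = lgb.LGBMRegressor if self.task == REGRESSION else lgb.LGBMClassifier
        self.model = cls(
            **self.params,
            random_state=self.seed,
            n_jobs=1,
            deterministic=True,
            force_row_wise=True,
            verbose=-1,
        )
        self.model.fit(np.asarray(X, dtype=np.float64), y)
        return self

    def predict_margin(self, X):
        X = np.asarray(X, dtype=np.float64)
        with _quiet_feature_names():
            if self.task == REGRESSION:
                return np.asarray(self.model.predict(X), dtype=np.float64)
            return np.asarray(self.model.predict(X, raw_score=True), dtype=np.float64)

    def shap_contributions(self, X):
        with _quiet_feature_names():
            return np.asarray(
                self.model.predict(np.asarray(X, dtype=np.float64), pred_contrib=True),
                dtype=np.float64,
            )


def _sample_candidate(rng: np.random.Generator, task: str) -> _BaseLearner:
    """Draw one randomized candidate from the search space."""
    seed = int(rng.integers(0, 2**31 - 1))
    common = {
        "n_estimators": int(rng.integers(80, 301)),
        "learning_rate": float(10 ** rng.uniform(-1.6, -0.55)),
        "subsample": float(rng.uniform(0.7, 1.0)),
        "reg_lambda": float(10 ** rng.uniform(-2.0, 1.0)),
    }
    if rng.random() < 0.5:
        params = {
            **common,
            "max_depth": int(rng.integers(3, 9)),
            "min_child_weight": float(10 ** rng.uniform(0.0, 1.3)),
            "colsample_bytree": float(rng.uniform(0.6, 1.0)),
        }
        return XGBLearner(params, task, seed)
    params = {
        **common,
        "num_leaves": int(rng.integers(15, 64)),
        "min_child_samples": int(rng.integers(5, 31)),
        "colsample_bytree": float(rng.uniform(0.6, 1.0)),
        "subsample_freq": 1,
    }
    return LGBLearner(params, task, seed)


def _sigmoid(margin: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-margin))


def _pooled_score(task: str, y: np.ndarray, margin: np.ndarray) -> float:
    """Lower-is-better pooled objective on out-of-fold predictions."""
    if task == REGRESSION:
        return rmse(EvalPairs.from_sequences(y, margin))
    prob = np.clip(_sigmoid(margin), 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


class EnsembleModel:
    """Weighted additive combination of fitted learners.

    The ensemble margin is the weighted mean of member margins; for
    classification the probability is the sigmoid of that margin.  A
    single selected learner is the one-member special case.
    """

    def __init__(self, members: List[Tuple[float, _BaseLearner]], task: str):
        if not members:
            raise ModelingError("ensemble needs at least one member")
        total = sum(w for w, _ in members)
        self.members = [(w / total, m) for w, m in members]
        self.task = task

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        return sum(w * m.predict_margin(X) for w, m in self.members)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """pKi for regression; P(class=1) for classification."""
        margin = self.predict_margin(X)
        return margin if self.task == REGRESSION else _sigmoid(margin)

    def predict_class(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        if self.task != CLASSIFICATION:
            raise ModelingError("predict_class is only defined for classifiers")
        return (self.predict(X) >= threshold).astype(int)

    def shap_contributions(self, X: np.ndarray) -> np.ndarray:
        """Weighted combination of member TreeSHAP contributions; exact
        for the ensemble because the margin is additive in the members."""
        return sum(w * m.shap_contributions(X) for w, m in self.members)

    def describe(self) -> str:
        counts: Dict[str, int] = {}
        for _, m in self.members:
            counts[m.family] = counts.get(m.family, 0) + 1
        if len(self.members) == 1:
            return self.members[0][1].family
        inner = ", ".join(f"{v}x {k}" for k, v in sorted(counts.items()))
        return f"Ensemble model ({inner})"


@dataclass
class ModelBundle:
    """Everything needed to reproduce a trained endpoint model's
    predictions: the estimator, its exact descriptor vocabulary, the
    feature-filter report (with imputation medians), the
    applicability-domain reference, and the cross-validated metrics."""

    estimator: EnsembleModel
    descriptor_names: List[str]
    filter_report: FeatureFilterReport
    cv_metrics: CVMetrics
    config: TrainingConfig
    target: str = ""
    ad_reference: Optional[object] = None  # ADReference, attached after training
    descriptor_set: str = "rdkit-2d"
    leaderboard: List[Tuple[int, str, float]] = field(default_factory=list)
    oof_margin: Optional[np.ndarray] = None

    def leaderboard_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.leaderboard, columns=["candidate", "family", "cv_score"]
        )


def train(
    train_matrix: DescriptorMatrix,
    labels: Sequence[float],
    config: TrainingConfig,
    filter_report: Optional[FeatureFilterReport] = None,
    target: str = "",
) -> ModelBundle:
    """Search, cross-validate and ensemble; return the fitted bundle.

    ``train_matrix`` must already be feature-filtered (its columns are
    the model's descriptor vocabulary).  The returned bundle carries the
    pooled out-of-fold metrics of the selected candidate/ensemble and
    the final estimator refitted on all training rows.
    """
    X = np.asarray(train_matrix.values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ModelingError("label count does not match matrix rows")
    if np.unique(y).size < 2:
        raise ModelingError("labels are constant; nothing to learn")
    if config.task == CLASSIFICATION and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelingError("classification labels must be 0/1")

    master = np.random.default_rng(config.seed)
    fold_seed = int(master.integers(0, 2**31 - 1))
    folds = make_folds(X.shape[0], config.n_folds, fold_seed)

    candidates = [_sample_candidate(master, config.task) for _ in range(config.search_budget)]

    # Out-of-fold margins for every candidate under the shared folds.
    oof = np.zeros((len(candidates), X.shape[0]), dtype=float)
    scores: List[float] = []
    t0 = time.monotonic()
    for ci, cand in enumerate(candidates):
        for fold in range(config.n_folds):
            val = folds == fold
            fitted = cand.clone().fit(X[~val], y[~val])
            oof[ci, val] = fitted.predict_margin(X[val])
        scores.append(_pooled_score(config.task, y, oof[ci]))
        if config.time_limit is not None and time.monotonic() - t0 > config.time_limit:
            oof = oof[: ci + 1]
            candidates = candidates[: ci + 1]
            break

    leaderboard = sorted(
        [(i, candidates[i].family, s) for i, s in enumerate(scores)], key=lambda t: t[2]
    )

    # Greedy forward selection with replacement on the OOF margins.
    picks: List[int] = [leaderboard[0][0]]
    margin_sum = oof[picks[0]].copy()
    best_score = _pooled_score(config.task, y, margin_sum)
    while len(picks) < MAX_ENSEMBLE_PICKS:
        trial_scores = [
            _pooled_score(config.task, y, (margin_sum + oof[i]) / (len(picks) + 1))
            for i in range(len(candidates))
        ]
        best_i = int(np.argmin(trial_scores))
        if trial_scores[best_i] + 1e-12 >= best_score:
            break
        picks.append(best_i)
        margin_sum = margin_sum + oof[best_i]
        best_score = trial_scores[best_i]

    ensemble_oof = margin_sum / len(picks)

    # Refit each distinct member on the full training data.
    weights: Dict[int, int] = {}
    for i in picks:
        weights[i] = weights.get(i, 0) + 1
    members = [
        (float(w), candidates[i].clone().fit(X, y)) for i, w in sorted(weights.items())
    ]
    estimator = EnsembleModel(members, config.task)

    cv = _cv_metrics_from_oof(config.task, y, ensemble_oof, folds, config.n_folds)

    if filter_report is None:
        filter_report = FeatureFilterReport(
            kept=list(train_matrix.descriptor_names),
            dropped_constant=[],
            dropped_correlated=[],
            correlation_threshold=float("nan"),
            medians={
                n: float(np.nanmedian(X[:, j]))
                for j, n in enumerate(train_matrix.descriptor_names)
            },
        )
    return ModelBundle(
        estimator=estimator,
        descriptor_names=list(train_matrix.descriptor_names),
        filter_report=filter_report,
        cv_metrics=cv,
        config=config,
        target=target,
        leaderboard=leaderboard,
        oof_margin=ensemble_oof,
    )


def _cv_metrics_from_oof(
    task: str, y: np.ndarray, oof_margin: np.ndarray, folds: np.ndarray, n_folds: int
) -> CVMetrics:
    if task == REGRESSION:
        pooled = EvalPairs.from_sequences(y, oof_margin)
        per_rmse, per_r2 = [], []
        for fold in range(n_folds):
            sel = folds == fold
            pairs = EvalPairs.from_sequences(y[sel], oof_margin[sel])
            per_rmse.append(rmse(pairs))
            try:
                per_r2.append(r_squared(pairs))
            except Exception:
                per_r2.append(float("nan"))
        return CVMetrics(
            task=REGRESSION,
            rmse_cv=rmse(pooled),
            r2_cv=r_squared(pooled),
            per_fold={"rmse": per_rmse, "r2": per_r2},
        )
    prob = _sigmoid(oof_margin)
    pred = (prob >= 0.5).astype(int)
    cm = ConfusionMatrix.from_labels(y.astype(int), pred)
    metrics = classification_metrics(cm)
    per_acc = []
    for fold in range(n_folds):
        sel = folds == fold
        per_acc.append(float(np.mean(pred[sel] == y[sel].astype(int))))
    metrics.per_fold = {"accuracy": per_acc}
    return metrics


def evaluate_test(
    bundle: ModelBundle,
    test_matrix: DescriptorMatrix,
    test_labels: Sequence[float],
) -> CVMetrics:
    """Score a bundle on an external test set.

    ``test_matrix`` must already be filtered with the bundle's own
    filter report (same columns, same order); the bundle's metrics
    object is updated in place with the test-set fields and returned.
    """
    if list(test_matrix.descriptor_names) != list(bundle.descriptor_names):
        raise ModelingError(
            "test matrix descriptors do not match the bundle "
            "(apply the bundle's filter_report first)"
        )
    y = np.asarray(test_labels, dtype=float)
    if y.size == 0:
        raise ModelingError("test set is empty")
    if y.shape[0] != test_matrix.n_molecules:
        raise ModelingError("test label count does not match matrix rows")

    metrics = bundle.cv_metrics
    if bundle.config.task == REGRESSION:
        pairs = EvalPairs.from_sequences(y, bundle.estimator.predict(test_matrix.values))
        metrics.rmse_test = rmse(pairs)
        metrics.r2_test = r_squared(pairs)
    else:
        pred = bundle.estimator.predict_class(test_matrix.values)
        cm = ConfusionMatrix.from_labels(y.astype(int), pred)
        test = classification_metrics(cm)
        metrics.accuracy_test = test.accuracy
        metrics.precision_test = test.precision
        metrics.recall_test = test.recall
        metrics.f1_test = test.f1
        metrics.mcc_test = test.mcc
        metrics.degenerate = metrics.degenerate or test.degenerate
    return metrics
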