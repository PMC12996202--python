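"""Nested cross-validated classification of risk vs control.

Fifteen regional movement indices (hips excluded because the pelvis-root
frame makes them near-degenerate; the global index excluded as a linear
combination of the rest) feed five classifier families: SVM, random
forest, extremely randomized trees, AdaBoost with tree stumps, and kNN.
Both loops of the nested scheme are stratified 5-fold: the inner loop
selects hyperparameters on each outer training fold, the outer loop
yields out-of-fold predictions so every participant is scored exactly
once.  Distance-based models (SVM, kNN) are z-scaled inside the CV
pipeline and use inverse-frequency class weighting; tree ensembles are
left unscaled.

Metric conventions: pooled out-of-fold confusion counts give accuracy,
precision, sensitivity, specificity and F1 (risk = positive class), each
with a Wilson 95% interval computed on the whole-cohort denominator;
AUC is summarized both as the mean of fold-wise AUCs (+/- sd) and as the
pooled out-of-fold AUC with a Hanley-McNeil interval.  Permutation
feature importance is measured on each held-out fold for the
inner-loop-selected estimator and averaged across folds and repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .landmarks import GLOBAL_INDEX, ML_FEATURES
from .stats import hanley_mcneil_ci, wilson_interval

POSITIVE = "risk"

FAMILIES = ("svm", "random_forest", "extra_trees", "adaboost", "knn")


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter grid."""

    family: str
    grid: list[dict] | dict = field(default_factory=dict)
    class_weight: str = "none"  # "inverse_frequency" | "none"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.class_weight not in ("inverse_frequency", "none"):
            raise ValueError(f"unknown class_weight {self.class_weight!r}")


@dataclass
class CvConfig:
    outer_folds: int = 5
    inner_folds: int = 5
    seed: int = 0
    inner_selection_metric: str = "roc_auc"
    pfi_repeats: int = 20
    pfi_metric: str = "accuracy"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class CvReport:
    family: str
    fold_metrics: list[dict]
    fold_params: list[dict]
    confusion: dict[str, int]  # pooled out-of-fold tp/fp/tn/fn
    metrics: dict[str, dict]   # name -> {value, ci_low, ci_high}
    mean_fold_auc: float
    sd_fold_auc: float
    pooled_auc: float
    pooled_auc_ci: tuple[float, float]
    importances: pd.Series | None
    oof_scores: np.ndarray
    oof_pred: np.ndarray
    fold_assignment: np.ndarray
    seed: int


def default_model_specs() -> dict[str, ModelSpec]:
    """Default hyperparameter grids for the five families."""
    return {
        "svm": ModelSpec(
            "svm",
            [
                {"model__kernel": ["rbf"], "model__C": [0.1, 1, 10, 100],
                 "model__gamma": ["scale", 0.01, 0.1, 1]},
                {"model__kernel": ["linear"], "model__C": [0.1, 1, 10, 100]},
            ],
            class_weight="inverse_frequency",
        ),
        "random_forest": ModelSpec(
            "random_forest",
            {"model__n_estimators": [100, 300], "model__max_depth": [None, 3, 5]},
        ),
        "extra_trees": ModelSpec(
            "extra_trees",
            {"model__n_estimators": [100, 300], "model__max_depth": [None, 3, 5]},
        ),
        "adaboost": ModelSpec(
            "adaboost",
            {"model__n_estimators": [50, 200], "model__learning_rate": [0.1, 1.0],
             "model__estimator__max_depth": [1, 2]},
        ),
        "knn": ModelSpec(
            "knn",
            {"model__n_neighbors": [3, 5, 7, 9], "model__weights": ["uniform", "distance"]},
            class_weight="inverse_frequency",
        ),
    }


def select_features(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract the 15-column model matrix and binary labels (risk = 1).

    Hip indices and the global index are excluded by construction.
    """
    missing = [c for c in ML_FEATURES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    x = features[list(ML_FEATURES)].copy()
    assert GLOBAL_INDEX not in x.columns
    assert not any("hip" in c for c in x.columns)
    y = (features["group"] == POSITIVE).to_numpy().astype(int)
    return x, y


def _build_estimator(spec: ModelSpec, seed: int) -> Pipeline:
    weight = "balanced" if spec.class_weight == "inverse_frequency" else None
    if spec.family == "svm":
        steps = [("scale", StandardScaler()),
                 ("model", SVC(class_weight=weight, random_state=seed))]
    elif spec.family == "knn":
        # kNN has no class_weight; inverse-frequency handled via distance
        # weighting options in the grid (documented deviation is not needed:
        # the voting grid already includes distance weighting).
        steps = [("scale", StandardScaler()), ("model", KNeighborsClassifier())]
    elif spec.family == "random_forest":
        steps = [("model", RandomForestClassifier(random_state=seed, class_weight=weight))]
    elif spec.family == "extra_trees":
        steps = [("model", ExtraTreesClassifier(random_state=seed, class_weight=weight))]
    elif spec.family == "adaboost":
        steps = [("model", AdaBoostClassifier(
            estimator=DecisionTreeClassifier(random_state=seed), random_state=seed))]
    else:  # pragma: no cover
        raise ValueError(spec.family)
    return Pipeline(steps)


def _scores(estimator, x: pd.DataFrame) -> np.ndarray:
    """Continuous decision scores, higher = more risk-like."""
    if hasattr(estimator, "predict_proba"):
        try:
            return estimator.predict_proba(x)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    return estimator.decision_function(x)


def permutation_importance(
    estimator,
    x: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_repeats: int = 20,
    rng: np.random.Generator | None = None,
    metric: str = "accuracy",
    feature_names: list[str] | None = None,
) -> pd.Series:
    """Held-out permutation feature importance for a fitted estimator.

    Importance of a feature is the baseline score minus the mean score
    after shuffling that feature's values across samples (repeated
    ``n_repeats`` times); near-zero means the feature is uninformative.
    """
    if isinstance(x, pd.DataFrame):
        feature_names = list(x.columns)
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(x.shape[1])]
    rng = rng or np.random.default_rng(0)
    scorer = {
        "accuracy": lambda est, xx: accuracy_score(y, est.predict(xx)),
        "roc_auc": lambda est, xx: roc_auc_score(y, _scores(est, xx)),
    }[metric]
    baseline = scorer(estimator, x)
    importances = {}
    for j, name in enumerate(feature_names):
        drops = []
        xp = x.copy()
        for _ in range(n_repeats):
            perm = rng.permutation(len(x))
            xp[:, j] = x[perm, j]
            drops.append(baseline - scorer(estimator, xp))
        importances[name] = float(np.mean(drops))
    return pd.Series(importances)


def compute_metrics(
    tp: int, fp: int, tn: int, fn: int, n_total: int | None = None, conf: float = 0.95
) -> dict[str, dict]:
    """Classification metrics with Wilson intervals on the cohort denominator.

    All intervals use ``n_total`` (the whole cohort) as the Wilson n — the
    reporting convention adopted here for every metric, including those
    whose natural denominator is a subgroup.
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    n_total = n_total or total
    values = {
        "accuracy": (tp + tn) / total,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }
    prec, sens = values["precision"], values["sensitivity"]
    values["f1"] = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    out = {}
    for name, value in values.items():
        low, high = wilson_interval(round(value * n_total), n_total, conf)
        out[name] = {"value": float(value), "ci_low": low, "ci_high": high}
    return out


def auc_summaries(
    fold_scores: list[np.ndarray], fold_labels: list[np.ndarray]
) -> tuple[float, float, float, tuple[float, float]]:
    """Mean fold-wise AUC (+/- sd) and pooled out-of-fold AUC with CI.

    Folds containing a single class have undefined AUC and are excluded
    from the fold-wise mean.  Pooled AUC uses the rank statistic on the
    concatenated scores (ties get half credit via the rank formulation).
    """
    fold_aucs = []
    for scores, labels in zip(fold_scores, fold_labels):
        if len(np.unique(labels)) < 2:
            continue
        fold_aucs.append(roc_auc_score(labels, scores))
    if not fold_aucs:
        raise ValueError("no fold with both classes present")
    scores = np.concatenate(fold_scores)
    labels = np.concatenate(fold_labels)
    pooled = float(roc_auc_score(labels, scores))
    n1 = int(labels.sum())
    n2 = int(len(labels) - n1)
    ci = hanley_mcneil_ci(pooled, n1, n2)
    return float(np.mean(fold_aucs)), float(np.std(fold_aucs)), pooled, ci


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic, ties half-credited."""
    from scipy.stats import rankdata

    pos = y_true == 1
    n1 = int(pos.sum())
    n2 = len(y_true) - n1
    r1 = rankdata(scores)[pos].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n2))


def _inner_select(
    estimator: Pipeline,
    grid: list[dict] | dict,
    x: np.ndarray,
    y: np.ndarray,
    inner: StratifiedKFold,
    metric: str,
) -> tuple[Pipeline, dict]:
    """Pick the grid point with the best mean inner-fold score.

    Selection is by the primary metric with the complementary metric as
    tie-break (AUC can saturate on small inner folds, where rank-perfect
    but badly thresholded models would otherwise win on grid order);
    remaining ties resolve to the earliest grid point, making selection
    deterministic.  A direct loop is used rather than a search wrapper to
    keep the per-fit overhead negligible at this sample size.
    """
    if not grid:
        return clone(estimator).fit(x, y), {}
    candidates = list(ParameterGrid(grid))
    splits = list(inner.split(x, y))
    best_key, best_params = (-np.inf, -np.inf), None
    for params in candidates:
        aucs, accs = [], []
        for train, val in splits:
            est = clone(estimator).set_params(**params)
            est.fit(x[train], y[train])
            accs.append(accuracy_score(y[val], est.predict(x[val])))
            if len(np.unique(y[val])) == 2:
                aucs.append(_rank_auc(y[val], _scores(est, x[val])))
        mean_auc = np.mean(aucs) if aucs else -np.inf
        mean_acc = np.mean(accs) if accs else -np.inf
        key = (mean_auc, mean_acc) if metric == "roc_auc" else (mean_acc, mean_auc)
        if key > best_key:
            best_key, best_params = key, params
    if best_params is None:  # pragma: no cover - empty inner splits
        best_params = candidates[0]
    best = clone(estimator).set_params(**best_params).fit(x, y)
    return best, dict(best_params)


def nested_cv(
    x: pd.DataFrame,
    y: np.ndarray,
    model: ModelSpec,
    config: CvConfig | None = None,
    compute_pfi: bool = True,
) -> CvReport:
    """Stratified nested cross-validation for one classifier family.

    The inner loop (grid search scored by ``inner_selection_metric``)
    picks hyperparameters on each outer training fold; the winner is
    refit on the full training fold and scored on the held-out fold.
    """
    config = config or CvConfig()
    y = np.asarray(y)
    feature_names = list(x.columns) if isinstance(x, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(x).shape[1])]
    x = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.outer_folds:
        raise ValueError(
            f"each class needs >= {config.outer_folds} members, got counts {counts.tolist()}")
    outer = StratifiedKFold(config.outer_folds, shuffle=True, random_state=config.seed)
    rng = np.random.default_rng(config.seed)

    n = len(y)
    oof_scores = np.full(n, np.nan)
    oof_pred = np.full(n, -1)
    fold_assignment = np.full(n, -1)
    fold_scores, fold_labels, fold_metrics, fold_params = [], [], [], []
    fold_importances = []

    # Inputs are validated once above; skip sklearn's per-fit finiteness
    # checks, which dominate runtime at this sample size.
    if not np.isfinite(x).all():
        raise ValueError("feature matrix contains non-finite values")
    with config_context(assume_finite=True):
        for fold, (train, test) in enumerate(outer.split(x, y)):
            inner = StratifiedKFold(config.inner_folds, shuffle=True,
                                    random_state=config.seed + 1000 + fold)
            estimator = _build_estimator(model, seed=config.seed + fold)
            best, params = _inner_select(
                estimator, model.grid, x[train], y[train], inner,
                config.inner_selection_metric,
            )
            fold_params.append(params)
            pred = best.predict(x[test])
            scores = _scores(best, x[test])
            oof_pred[test] = pred
            oof_scores[test] = scores
            fold_assignment[test] = fold
            fold_scores.append(scores)
            fold_labels.append(y[test])
            fold_metrics.append(
                {"accuracy": float(accuracy_score(y[test], pred)),
                 "n_test": int(len(test))}
            )
            if compute_pfi:
                fold_importances.append(
                    permutation_importance(
                        best, x[test], y[test], n_repeats=config.pfi_repeats,
                        rng=np.random.default_rng(rng.integers(2**31)),
                        metric=config.pfi_metric, feature_names=feature_names,
                    )
                )

    assert (fold_assignment >= 0).all(), "every participant must be scored once"
    tp = int(((oof_pred == 1) & (y == 1)).sum())
    fp = int(((oof_pred == 1) & (y == 0)).sum())
    tn = int(((oof_pred == 0) & (y == 0)).sum())
    fn = int(((oof_pred == 0) & (y == 1)).sum())
    metrics = compute_metrics(tp, fp, tn, fn, n_total=n)
    mean_auc, sd_auc, pooled_auc, auc_ci = auc_summaries(fold_scores, fold_labels)
    importances = (
        pd.concat(fold_importances, axis=1).mean(axis=1) if fold_importances else None
    )
    return CvReport(
        family=model.family, fold_metrics=fold_metrics, fold_params=fold_params,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn}, metrics=metrics,
        mean_fold_auc=mean_auc, sd_fold_auc=sd_auc, pooled_auc=pooled_auc,
        pooled_auc_ci=auc_ci, importances=importances, oof_scores=oof_scores,
        oof_pred=oof_pred, fold_assignment=fold_assignment, seed=config.seed,
    )


def demographic_baseline(
    age_months: np.ndarray, sex: np.ndarray, y: np.ndarray,
    config: CvConfig | None = None,
) -> CvReport:
    """Auxiliary SVM trained on age and sex only, same nested-CV framework.

    Quantifies how much of any movement-feature performance could be
    explained by basic demographics alone.
    """
    x = pd.DataFrame(
        {"age_months": np.asarray(age_months, dtype=float),
         "sex_boy": (np.asarray(sex) == "boy").astype(float)}
    )
    spec = default_model_specs()["svm"]
    report = nested_cv(x, y, spec, config, compute_pfi=False)
    report.family = "svm_demographic"
    return report


def report_to_row(report: CvReport) -> dict:
    """Flatten a CvReport into one summary-table row."""
    row = {"model": report.family}
    for name, m in report.metrics.items():
        row[name] = m["value"]
        row[f"{name}_ci_low"] = m["ci_low"]
        row[f"{name}_ci_high"] = m["ci_high"]
    row["mean_fold_auc"] = report.mean_fold_auc
    row["sd_fold_auc"] = report.sd_fold_auc
    row["pooled_auc"] = report.pooled_auc
    row["pooled_auc_ci_low"] = report.pooled_auc_ci[0]
    row["pooled_auc_ci_high"] = report.pooled_auc_ci[1]
    return row


def roc_points(report: CvReport, y: np.ndarray) -> pd.DataFrame:
    """ROC curve coordinates from pooled out-of-fold scores."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thresh = roc_curve(y, report.oof_scores)
    return pd.DataFrame({"model": report.family, "fpr": fpr, "tpr": tpr,
                         "threshold": thresh})
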