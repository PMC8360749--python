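"""Ensemble classification, importance-based feature selection and the
screening-test evaluation metrics.

The learners are standard tree ensembles (bagging, random forest, AdaBoost,
gradient boosting, XGBoost); this module owns what matters scientifically
around them: group-aware stratified cross-validation (a scan and all of its
augmented copies share a ``source_id`` and must land in the same fold),
pooled confusion counts, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total, and AUC as the Mann-Whitney rank statistic over
pooled out-of-fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.tree import DecisionTreeClassifier

from .feature_table import FeatureTable

__all__ = [
    "MODEL_KINDS",
    "ImportanceRanking",
    "ConfusionCounts",
    "EvaluationReport",
    "train",
    "importances",
    "select_top_k",
    "rank_auc",
    "evaluate",
]

MODEL_KINDS = ("bagging", "random_forest", "adaboost", "gradient_boosting", "xgboost")


@dataclass
class ImportanceRanking:
    """(feature, weight) pairs, descending by weight; weights sum to 1.
    Ties are broken alphabetically by feature name."""

    items: list[tuple[str, float]]

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.items])
        if (weights < 0).any():
            raise ValueError("importance weights must be >= 0")
        order = sorted(range(len(self.items)), key=lambda k: (-self.items[k][1], self.items[k][0]))
        self.items = [self.items[k] for k in order]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0


@dataclass
class EvaluationReport:
    confusion: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    folds: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.__dict__,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "folds": self.folds,
        }


def _make_model(model_kind: str, hyperparams: dict | None, seed: int):
    hp = dict(hyperparams or {})
    if model_kind == "bagging":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=hp.pop("n_estimators", 100),
            random_state=seed,
            **hp,
        )
    if model_kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 200), random_state=seed, **hp
        )
    if model_kind == "adaboost":
        return AdaBoostClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    if model_kind == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    if model_kind == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=hp.pop("n_estimators", 200),
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
            **hp,
        )
    raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")


def train(
    table: FeatureTable,
    model_kind: str = "gradient_boosting",
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit one ensemble on the whole table; deterministic for a fixed seed."""
    y = table.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both classes present")
    if counts.min() < 2:
        raise ValueError("training requires >= 2 samples per class")
    model = _make_model(model_kind, hyperparams, seed)
    model.fit(table.X, y)
    model._radtex_features = list(table.feature_names)  # provenance for importances
    return model


def importances(model, table: FeatureTable) -> ImportanceRanking:
    """Normalized impurity-based feature importances, descending."""
    names = table.feature_names
    if isinstance(model, BaggingClassifier):
        per_tree = np.array([est.feature_importances_ for est in model.estimators_])
        imp = per_tree.mean(axis=0)
    elif hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise TypeError(f"{type(model).__name__} exposes no intrinsic feature importances")
    if len(imp) != len(names):
        raise ValueError("model was fitted on a different feature set")
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    return ImportanceRanking(items=list(zip(names, imp.tolist())))


def select_top_k(ranking: ImportanceRanking, k: int) -> list[str]:
    if not 1 <= k <= len(ranking.items):
        raise ValueError(f"k must be in [1, {len(ranking.items)}], got {k}")
    return ranking.names[:k]


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic (midranks for ties)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(
    table: FeatureTable,
    model_kind: str = "gradient_boosting",
    hyperparams: dict | None = None,
    folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Group-aware stratified k-fold CV with pooled out-of-fold metrics.

    All rows sharing a ``source_id`` are assigned to the same fold, so a scan
    never shares folds with its augmented copies. A fold whose training part
    is single-class is skipped with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    # canonicalize row order so evaluation is invariant to table row shuffling
    df = table.df.sort_values(
        by=["source_id"] + table.feature_names, kind="mergesort"
    ).reset_index(drop=True)
    table = FeatureTable(df=df)
    X, y, groups = table.X, table.y, table.groups
    for cls in np.unique(y):
        n_groups = len(set(groups[y == cls]))
        if n_groups < folds:
            raise ValueError(
                f"class {cls} has only {n_groups} source groups; "
                f"cannot form {folds} group-aware folds"
            )
    splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_true, pooled_pred, pooled_score = [], [], []
    fold_reports = []
    for fold_idx, (tr, te) in enumerate(splitter.split(X, y, groups)):
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"fold {fold_idx}: single-class training set, skipped", stacklevel=2)
            continue
        assert not set(groups[tr]) & set(groups[te]), "source_id leaked across folds"
        model = _make_model(model_kind, hyperparams, seed)
        model.fit(X[tr], y[tr])
        score = model.predict_proba(X[te])[:, 1]
        pred = (score >= 0.5).astype(int)
        pooled_true.append(y[te])
        pooled_pred.append(pred)
        pooled_score.append(score)
        fold_reports.append(
            {"fold": fold_idx, "n_test": int(len(te)),
             "accuracy": float((pred == y[te]).mean())}
        )
    if not pooled_true:
        raise ValueError("every fold was skipped; cannot evaluate")
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    sc = np.concatenate(pooled_score)
    cm = ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )
    report = EvaluationReport(
        confusion=cm,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        auc=rank_auc(yt, sc),
        folds=fold_reports,
    )
    assert abs(report.accuracy - (cm.tp + cm.tn) / cm.total) < 1e-12
    if 0 < cm.tp + cm.fn and 0 < cm.tn + cm.fp:
        lo, hi = sorted((report.sensitivity, report.specificity))
        assert lo - 1e-12 <= report.accuracy <= hi + 1e-12
    return report
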