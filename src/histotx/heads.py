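"""Classification heads, patient-stratified cross-validation and metrics.

End classifiers on slide embeddings are L2-regularised logistic regressions
with C = 7, max_iter = 10,000 and balanced class weights.  All trainings
share one 5-fold split, stratified on the output variable at the *patient*
level, so that no patient's slides ever straddle a train/test boundary and
every model type is compared on identical folds.  External cohorts are
scored by averaging the probabilities of the five fold models.

Evaluation reports AUC, balanced accuracy and macro-averaged F1, at slide
level (per fold, mean +/- sd) and at patient level (mean probability over a
patient's slides, pooled out-of-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold


class FoldError(ValueError):
    """Invalid fold construction or a fold with a single class."""


class MetricError(ValueError):
    """Metric undefined for the given labels."""


@dataclass
class HeadConfig:
    C: float = 7.0
    max_iterations: int = 10_000
    class_weighting: str = "balanced"  # "balanced" | "none"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")


@dataclass
class FoldPlan:
    """Patient-level stratified fold assignment, shared across all trainings."""

    k: int
    assignment: dict[str, int]  # patient_id -> fold index

    def fold_of(self, patient_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[p] for p in patient_ids])


@dataclass
class EvalReport:
    """Per-fold slide-level metrics and pooled patient-level metrics."""

    fold_auc: list[float]
    fold_balanced_accuracy: list[float]
    fold_f1_macro: list[float]
    patient_auc: float
    patient_balanced_accuracy: float
    patient_f1_macro: float

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.fold_auc))

    @property
    def balanced_accuracy(self) -> float:
        return float(np.mean(self.fold_balanced_accuracy))

    @property
    def f1_macro(self) -> float:
        return float(np.mean(self.fold_f1_macro))

    def summary(self) -> dict[str, float]:
        return {
            "slide_auc_mean": self.auc,
            "slide_auc_sd": self.auc_sd,
            "slide_balanced_accuracy_mean": self.balanced_accuracy,
            "slide_f1_macro_mean": self.f1_macro,
            "patient_auc": self.patient_auc,
            "patient_balanced_accuracy": self.patient_balanced_accuracy,
            "patient_f1_macro": self.patient_f1_macro,
        }


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def balanced_accuracy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean of sensitivity and specificity."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("balanced accuracy needs both classes present")
    return float(balanced_accuracy_score(labels, predictions))


def f1_macro(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Unweighted mean of per-class F1 scores."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("macro-F1 needs both classes present")
    return float(f1_score(labels, predictions, average="macro", zero_division=0))


def stratified_patient_folds(
    patient_labels: pd.Series, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified K folds over patients (one unit per patient).

    ``patient_labels`` maps patient_id -> binary label.  Per-fold positive
    counts differ by at most 1 from perfect stratification; deterministic
    given ``seed``.
    """
    patient_labels = pd.Series(patient_labels)
    y = patient_labels.to_numpy()
    n_rare = min(np.sum(y == v) for v in np.unique(y))
    if len(np.unique(y)) < 2 or n_rare < k:
        raise FoldError(
            f"need >= {k} patients of the rarer label, got {n_rare}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    pids = np.asarray(patient_labels.index)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[pids[i]] = fold
    return FoldPlan(k=k, assignment=assignment)


def train_head(X: np.ndarray, y: np.ndarray, config: HeadConfig | None = None):
    """Fit the L2 logistic head (C=7, max_iter=10,000, balanced by default)."""
    if config is None:
        config = HeadConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise FoldError("head training needs both classes")
    clf = LogisticRegression(  # default penalty: L2
        C=config.C,
        max_iter=config.max_iterations,
        class_weight="balanced" if config.class_weighting == "balanced" else None,
    )
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def _patient_level(
    patient_ids: np.ndarray, y: np.ndarray, proba: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate slide probabilities to patients by the mean."""
    df = pd.DataFrame({"patient": patient_ids, "y": y, "p": proba})
    agg = df.groupby("patient").agg(y=("y", "first"), p=("p", "mean"))
    return agg["y"].to_numpy(), agg["p"].to_numpy()


def cross_validate(
    items: Sequence,
    y: np.ndarray,
    patient_ids: Sequence[str],
    plan: FoldPlan,
    fit: Callable,
    predict: Callable,
    threshold: float = 0.5,
) -> tuple[EvalReport, np.ndarray, list]:
    """Generic K-fold evaluation honouring the shared patient-level plan.

    ``items`` is indexable training material (an (n, D) embedding matrix or a
    list of MIL bags), aligned with ``y`` and ``patient_ids`` per slide.
    ``fit(items_subset, y_subset) -> model`` and
    ``predict(model, items_subset) -> positive-class probabilities``.

    Returns the report, per-slide out-of-fold probabilities, and the k fold
    models (for fold-ensembled external inference).
    """
    y = np.asarray(y)
    patient_ids = np.asarray(patient_ids)
    folds = plan.fold_of(patient_ids)
    oof = np.full(len(y), np.nan)
    models = []
    fold_aucs, fold_bas, fold_f1s = [], [], []
    for fold in range(plan.k):
        test = folds == fold
        train = ~test
        # leakage guard: a patient is entirely in train or entirely in test
        assert not set(patient_ids[train]) & set(patient_ids[test])
        for name, sel in (("train", train), ("test", test)):
            if len(np.unique(y[sel])) < 2:
                raise FoldError(f"fold {fold}: single-class {name} split")
        items_train = _take(items, train)
        items_test = _take(items, test)
        model = fit(items_train, y[train])
        proba = np.asarray(predict(model, items_test), dtype=float)
        oof[test] = proba
        models.append(model)
        pred = (proba >= threshold).astype(int)
        fold_aucs.append(auc(y[test], proba))
        fold_bas.append(balanced_accuracy(y[test], pred))
        fold_f1s.append(f1_macro(y[test], pred))
    py, pp = _patient_level(patient_ids, y, oof)
    report = EvalReport(
        fold_auc=fold_aucs,
        fold_balanced_accuracy=fold_bas,
        fold_f1_macro=fold_f1s,
        patient_auc=auc(py, pp),
        patient_balanced_accuracy=balanced_accuracy(py, (pp >= threshold).astype(int)),
        patient_f1_macro=f1_macro(py, (pp >= threshold).astype(int)),
    )
    return report, oof, models


def _take(items, mask: np.ndarray):
    if isinstance(items, np.ndarray):
        return items[mask]
    idx = np.flatnonzero(mask)
    return [items[i] for i in idx]


def cross_validate_head(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence[str],
    plan: FoldPlan,
    config: HeadConfig | None = None,
) -> tuple[EvalReport, np.ndarray, list]:
    """K-fold evaluation of the logistic head on slide embeddings."""
    cfg = config or HeadConfig()
    return cross_validate(
        np.asarray(X, dtype=float),
        y,
        patient_ids,
        plan,
        fit=lambda Xt, yt: train_head(Xt, yt, cfg),
        predict=lambda m, Xt: m.predict_proba(Xt)[:, 1],
    )


def ensemble_inference(models: list, X: np.ndarray) -> np.ndarray:
    """Fold-ensembled external inference: arithmetic mean of the k models'
    positive-class probabilities."""
    if len(models) == 0:
        raise ValueError("need at least one model")
    X = np.asarray(X, dtype=float)
    dims = {m.coef_.shape[1] for m in models if hasattr(m, "coef_")}
    if dims and dims != {X.shape[1]}:
        raise ValueError(f"feature dimension mismatch: models {dims}, X {X.shape[1]}")
    probs = np.stack([m.predict_proba(X)[:, 1] for m in models])
    return probs.mean(axis=0)
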