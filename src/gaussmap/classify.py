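"""Hierarchical two-stage RBF-SVM classification and its evaluation.

Stage 1 separates normal controls (NC) from abnormal subjects (AD and MCI
pooled); stage 2, trained on abnormal subjects only, separates AD from MCI.
A test subject first passes stage 1; only if called abnormal does stage 2
assign AD or MCI. Decision values of both stages are kept for ROC analysis.

Each stage is a pipeline of Fisher selection -> z-scoring -> RBF-kernel SVM
(libsvm via scikit-learn), with k, C and gamma chosen by an inner
cross-validated grid search. Under cross-validation every fitted component
(descriptor value ranges, selection, scaler, grid search) is refitted on the
training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, \
    StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import FisherSelector

LABELS = ("NC", "MCI", "AD")


class InsufficientClassesError(ValueError):
    """Training requires all three diagnostic labels."""


@dataclass
class ClassifierConfig:
    """Hyper-parameter grids and cross-validation layout.

    gamma_scale entries are multiplied by 1/d (d = input feature count).
    k_grid entries above the feature count are dropped; None keeps all.
    """

    C_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_scale: tuple = (0.1, 1.0, 10.0)
    k_grid: tuple = (16, 32, 64, 128, None)
    inner_folds: int = 3
    folds: int = 5
    repeats: int = 5


@dataclass
class EvalReport:
    """Binary-stage evaluation: confusion counts, rates, ROC and AUC."""

    stage: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (n, 2) of (FPR, TPR)
    auc: float
    fold_accuracies: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage, "tp": self.tp, "tn": self.tn,
            "fp": self.fp, "fn": self.fn, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "auc": self.auc, "fold_accuracies": list(self.fold_accuracies),
            "roc_points": self.roc_points.tolist(),
        }


@dataclass
class HierarchicalModel:
    """Two fitted binary stages plus feature-pipeline provenance."""

    stage1: Pipeline  # NC (0) vs abnormal (1)
    stage2: Pipeline  # MCI (0) vs AD (1), fitted on abnormal subjects only
    provenance: dict = field(default_factory=dict)


def _stage_estimator(n_features: int, config: ClassifierConfig,
                     seed: int) -> GridSearchCV:
    pipe = Pipeline([
        ("select", FisherSelector()),
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf")),
    ])
    ks = [k for k in config.k_grid if k is None or k <= n_features]
    if None not in ks:
        ks.append(None)
    grid = {
        "select__k": ks,
        "svc__C": list(config.C_grid),
        "svc__gamma": [g / n_features for g in config.gamma_scale],
    }
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                            random_state=seed % (2 ** 31))
    return GridSearchCV(pipe, grid, cv=inner, n_jobs=1)


def train_hierarchical(X: np.ndarray, y, config: ClassifierConfig | None = None,
                       seed: int = 0,
                       min_per_class: int = 5) -> HierarchicalModel:
    """Fit both stages on a cohort with all three labels present.

    ``min_per_class`` defaults to 5 for direct use; cross-validation relaxes
    it to the inner-fold count, the hard floor for the nested grid search.
    """
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    for lab in LABELS:
        if (y == lab).sum() < min_per_class:
            raise InsufficientClassesError(
                f"need >= {min_per_class} subjects of class {lab}, "
                f"got {(y == lab).sum()}")
    y1 = (y != "NC").astype(int)  # positive = abnormal
    gs1 = _stage_estimator(X.shape[1], config, seed)
    gs1.fit(X, y1)
    abn = y != "NC"
    y2 = (y[abn] == "AD").astype(int)  # positive = AD
    gs2 = _stage_estimator(X.shape[1], config, seed + 1)
    gs2.fit(X[abn], y2)
    prov = {
        "stage1_params": {k: v for k, v in gs1.best_params_.items()},
        "stage2_params": {k: v for k, v in gs2.best_params_.items()},
        "n_features": int(X.shape[1]),
    }
    return HierarchicalModel(stage1=gs1.best_estimator_,
                             stage2=gs2.best_estimator_, provenance=prov)


def predict_hierarchical(model: HierarchicalModel, X: np.ndarray):
    """Hierarchical labels plus both stages' decision values.

    A stage-1 decision value of exactly 0 breaks toward abnormal (favouring
    sensitivity to disease). Stage-2 decision values are computed for every
    subject so per-stage ROC can be assembled by the caller; they only enter
    the label when stage 1 calls the subject abnormal.
    """
    X = np.asarray(X, dtype=float)
    dv1 = model.stage1.decision_function(X)
    dv2 = model.stage2.decision_function(X)
    labels = np.where(dv1 >= 0, np.where(dv2 >= 0, "AD", "MCI"), "NC")
    return labels, dv1, dv2


def roc_curve(decision_values, truth) -> tuple[np.ndarray, float]:
    """ROC points from a threshold sweep, and the trapezoidal AUC.

    ``truth`` is binary (1/True = positive). The returned point list starts
    at (0, 0), ends at (1, 1) and is monotone in both coordinates; the AUC
    equals the normalised Mann-Whitney pairwise-win count.
    """
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC needs both classes present")
    scores = np.asarray(decision_values, dtype=float)
    if np.ptp(scores) == 0:  # single threshold: the chance diagonal
        points = np.array([[0.0, 0.0], [1.0, 1.0]])
        return points, 0.5
    fpr, tpr, _ = _sk_roc_curve(truth, scores)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# cross-validation

class MatrixDataset:
    """Fixed feature matrix: nothing to refit per fold."""

    def __init__(self, X, y, subject_ids=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.subject_ids = (np.asarray(subject_ids) if subject_ids is not None
                            else np.arange(len(self.y)).astype(str))

    def __len__(self) -> int:
        return len(self.y)

    def fit_fold(self, train_idx):
        return None

    def transform(self, idx, state):
        return self.X[idx]


@dataclass
class CVResult:
    stage1: EvalReport
    stage2: EvalReport
    overall_accuracy: float
    n_subjects: int
    predictions: list  # (repeat_fold, subject_id, truth, predicted)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "n_subjects": self.n_subjects,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
        }


def _binary_report(stage: str, truth: np.ndarray, pred: np.ndarray,
                   scores: np.ndarray, fold_accs: list) -> EvalReport:
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    points, auc_val = roc_curve(scores, truth)
    return EvalReport(
        stage=stage, tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / max(tp + tn + fp + fn, 1),
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        roc_points=points, auc=auc_val, fold_accuracies=fold_accs,
    )


def cross_validate(dataset, config: ClassifierConfig | None = None,
                   seed: int = 0) -> CVResult:
    """Repeated stratified k-fold evaluation of the hierarchical classifier.

    ``dataset`` provides labels plus per-fold feature construction
    (``fit_fold``/``transform``), so descriptor ranges and every other
    preprocessing step are derived from training subjects only. Per-stage
    reports pool out-of-fold decision values across folds and repeats;
    the stage-2 report is restricted to truly abnormal subjects (its
    eligible population). Deterministic for a fixed seed.
    """
    config = config or ClassifierConfig()
    y = dataset.y
    counts = {lab: int((y == lab).sum()) for lab in LABELS}
    if min(counts.values()) < config.folds:
        raise ValueError(
            f"smallest class {counts} cannot fill {config.folds} folds; "
            f"use fewer folds")
    rskf = RepeatedStratifiedKFold(n_splits=config.folds,
                                   n_repeats=config.repeats,
                                   random_state=seed % (2 ** 31))
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(config.folds * config.repeats) % (2 ** 31)
    truth1_all, pred1_all, dv1_all = [], [], []
    truth2_all, pred2_all, dv2_all = [], [], []
    s1_folds, s2_folds = [], []
    predictions = []
    n_correct = 0
    n_total = 0
    for fold_i, (tr, te) in enumerate(rskf.split(np.zeros(len(y)), y)):
        state = dataset.fit_fold(tr)
        Xtr = dataset.transform(tr, state)
        Xte = dataset.transform(te, state)
        model = train_hierarchical(Xtr, y[tr], config,
                                   seed=int(fold_seeds[fold_i]),
                                   min_per_class=max(2, config.inner_folds))
        pred, dv1, dv2 = predict_hierarchical(model, Xte)
        yt = y[te]
        n_correct += int((pred == yt).sum())
        n_total += len(te)
        for sid, t, p in zip(dataset.subject_ids[te], yt, pred):
            predictions.append((fold_i, str(sid), str(t), str(p)))
        t1 = (yt != "NC").astype(int)
        p1 = (dv1 >= 0).astype(int)
        truth1_all.append(t1); pred1_all.append(p1); dv1_all.append(dv1)
        s1_folds.append(float((t1 == p1).mean()))
        abn = yt != "NC"
        if abn.any():
            t2 = (yt[abn] == "AD").astype(int)
            p2 = (dv2[abn] >= 0).astype(int)
            truth2_all.append(t2); pred2_all.append(p2)
            dv2_all.append(dv2[abn])
            s2_folds.append(float((t2 == p2).mean()))
    stage1 = _binary_report("NC_vs_abnormal", np.concatenate(truth1_all),
                            np.concatenate(pred1_all),
                            np.concatenate(dv1_all), s1_folds)
    stage2 = _binary_report("AD_vs_MCI", np.concatenate(truth2_all),
                            np.concatenate(pred2_all),
                            np.concatenate(dv2_all), s2_folds)
    return CVResult(stage1=stage1, stage2=stage2,
                    overall_accuracy=n_correct / n_total,
                    n_subjects=len(y), predictions=predictions)
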