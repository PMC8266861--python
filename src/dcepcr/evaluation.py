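"""SVM classification on selected features and its evaluation.

The classifier is a z-score scaler plus SVM (linear kernel, C = 1 by
default — a conventional choice for high-dimension/low-n problems) with
the positive class being pCR; decision scores are oriented so larger means
more pCR-like. Evaluation follows the study design: leave-one-patient-out
scores on the fine-tuning cohort, a single fit for the independent test,
ROC/AUC, the Youden-index operating threshold, confusion metrics in
percent, subtype-stratified metrics, and optional integration of the four
clinical variables (ER, PgR, HER2, molecular subtype).

Fine-tuning LOO metrics are optimistically biased because the OSF itself
was derived using all fine-tuning patients; the independent test is the
unbiased surface. Every :class:`EvalReport` carries this note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "ModelSpec",
    "EvalReport",
    "PcrSvmClassifier",
    "loo_scores",
    "roc_auc",
    "youden_threshold",
    "confusion_metrics",
    "evaluate_loo",
    "independent_eval",
    "subtype_stratified_eval",
    "append_clinical",
    "CLINICAL_VARIABLES",
    "SUBTYPE_CODES",
]

OPTIMISM_NOTE = ("fine-tuning LOO metrics are optimistically biased: the OSF was "
                 "selected using all fine-tuning patients; the independent test "
                 "is the unbiased estimate")

CLINICAL_VARIABLES = ("er", "pgr", "her2", "subtype")
SUBTYPE_CODES = {"Luminal": 0, "HER2+": 1, "Triple Negative": 2}


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: which columns it sees and how the SVM is set up."""

    feature_set: str = "OSF-T1T2"
    kernel: str = "linear"
    C: float = 1.0
    use_clinical: bool = False
    seed: int = 0


@dataclass
class EvalReport:
    """ROC, AUC, Youden threshold and confusion metrics for one model."""

    auc: float
    youden_threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame
    scores: np.ndarray
    predictions: np.ndarray
    n_pos: int
    n_neg: int
    notes: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "scores": self.scores.tolist(),
            "predictions": self.predictions.tolist(),
            "notes": list(self.notes),
            "extras": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.extras.items()},
        }


class PcrSvmClassifier(ClassifierMixin, BaseEstimator):
    """z-score scaling + SVM; decision scores oriented toward pCR (= 1)."""

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 gamma: str = "scale", scale: bool = True, random_state: int = 0):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.scale = scale
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold has a single class")
        svc = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                  random_state=self.random_state)
        steps = ([StandardScaler()] if self.scale else []) + [svc]
        self.pipeline_ = make_pipeline(*steps)
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        X = validate_data(self, X, reset=False)
        return self.pipeline_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = validate_data(self, X, reset=False)
        return self.pipeline_.predict(X)


def _make_clf(spec: ModelSpec) -> PcrSvmClassifier:
    return PcrSvmClassifier(kernel=spec.kernel, C=spec.C, random_state=spec.seed)


def loo_scores(X: np.ndarray, y: np.ndarray, clinical: pd.DataFrame | None = None,
               spec: ModelSpec | None = None) -> np.ndarray:
    """Leave-one-patient-out decision scores.

    Scaling (and, when ``clinical`` is given, clinical encoding/imputation)
    is fit on each training fold only. A fold whose training set collapses
    to one class raises.
    """
    spec = spec or ModelSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if min((y == c).sum() for c in np.unique(y)) < 2 or len(np.unique(y)) != 2:
        raise ValueError("need at least 2 patients per class")
    scores = np.empty(n)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        if clinical is not None:
            Xa, _ = append_clinical(X, clinical, train_idx=tr)
        else:
            Xa = X
        clf = _make_clf(spec).fit(Xa[tr], y[tr])
        scores[i] = clf.decision_function(Xa[i:i + 1])[0]
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC points and AUC (concordant-pair fraction, ties half credit)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(roc_auc_score(labels, scores))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    s = np.unique(np.asarray(scores, float))
    if len(s) == 1:
        return np.array([s[0], s[0] + 1.0])
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores plus one
    threshold below and above all scores (prediction rule: positive when
    score >= threshold). Ties are broken toward higher specificity, then
    the higher threshold, so separable scores yield the gap midpoint.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for t in _candidate_thresholds(scores):
        sens = (pos >= t).mean() if len(pos) else 0.0
        spec = (neg < t).mean() if len(neg) else 0.0
        key = (sens + spec - 1.0, spec, t)
        if best is None or key > best:
            best = key
    return float(best[2])


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    """Accuracy/sensitivity/specificity in percent (1 decimal); score >= threshold is positive."""
    labels = np.asarray(labels)
    pred = np.asarray(scores, float) >= threshold
    pos, neg = labels == 1, labels == 0
    tp, fn = (pred & pos).sum(), (~pred & pos).sum()
    tn, fp = (~pred & neg).sum(), (pred & neg).sum()
    out = {
        "accuracy": round(100.0 * (tp + tn) / len(labels), 1),
        "sensitivity": round(100.0 * tp / (tp + fn), 1) if tp + fn else float("nan"),
        "specificity": round(100.0 * tn / (tn + fp), 1) if tn + fp else float("nan"),
    }
    return out


def _report(scores, labels, threshold) -> EvalReport:
    points, auc = roc_auc(scores, labels)
    m = confusion_metrics(scores, labels, threshold)
    labels = np.asarray(labels)
    return EvalReport(auc=auc, youden_threshold=float(threshold),
                      accuracy=m["accuracy"], sensitivity=m["sensitivity"],
                      specificity=m["specificity"], roc=points,
                      scores=np.asarray(scores, float),
                      predictions=(np.asarray(scores, float) >= threshold).astype(int),
                      n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()),
                      notes=[OPTIMISM_NOTE])


def evaluate_loo(X: np.ndarray, y: np.ndarray, clinical: pd.DataFrame | None = None,
                 spec: ModelSpec | None = None) -> EvalReport:
    """LOO scores pooled into one ROC; Youden threshold from the pooled scores."""
    scores = loo_scores(X, y, clinical=clinical, spec=spec)
    thr = youden_threshold(scores, y)
    return _report(scores, y, thr)


def independent_eval(X_train: np.ndarray, y_train: np.ndarray,
                     X_test: np.ndarray, y_test: np.ndarray,
                     clinical_train: pd.DataFrame | None = None,
                     clinical_test: pd.DataFrame | None = None,
                     spec: ModelSpec | None = None,
                     threshold_from: str = "test") -> EvalReport:
    """Fit once on all training patients, score the independent test.

    The Youden threshold is taken from the test-set ROC by default
    (``threshold_from="test"``) or from the training LOO-free fit
    (``"train"``); both are reported in ``extras``.
    """
    spec = spec or ModelSpec()
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    if X_train.shape[1] == 0 and clinical_train is None:
        raise ValueError(
            "no features to train on (empty OSF): rerun selection with a "
            "larger alpha or a stronger class effect")
    if clinical_train is not None:
        n_tr = len(X_train)
        stacked = pd.concat([clinical_train, clinical_test], ignore_index=True)
        Xall, _ = append_clinical(np.vstack([X_train, X_test]), stacked,
                                  train_idx=np.arange(n_tr))
        X_train, X_test = Xall[:n_tr], Xall[n_tr:]
    clf = _make_clf(spec).fit(X_train, y_train)
    scores = clf.decision_function(X_test)
    train_scores = clf.decision_function(X_train)
    thr_test = youden_threshold(scores, y_test)
    thr_train = youden_threshold(train_scores, y_train)
    thr = thr_test if threshold_from == "test" else thr_train
    rep = _report(scores, y_test, thr)
    rep.notes = ["single model fit on the full training cohort; threshold from "
                 f"{threshold_from} ROC"]
    rep.extras.update({
        "threshold_test_roc": thr_test,
        "threshold_train_roc": thr_train,
        "metrics_at_train_threshold": confusion_metrics(scores, y_test, thr_train),
    })
    return rep


def subtype_stratified_eval(scores: np.ndarray, labels: np.ndarray,
                            subtype: pd.Series | np.ndarray, threshold: float) -> dict:
    """Confusion metrics per molecular subtype at the global threshold.

    Patients with missing subtype are excluded and counted. A stratum with
    one class only reports the undefined metric as None.
    """
    subtype = pd.Series(np.asarray(subtype, dtype=object))
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    missing = subtype.isna().to_numpy()
    out = {"n_excluded_missing_subtype": int(missing.sum()), "strata": {}}
    for name in sorted(subtype.dropna().unique()):
        m = (subtype == name).to_numpy()
        met = confusion_metrics(scores[m], labels[m], threshold)
        met = {k: (None if isinstance(v, float) and np.isnan(v) else v)
               for k, v in met.items()}
        met["n"] = int(m.sum())
        met["n_pos"] = int((labels[m] == 1).sum())
        met["n_neg"] = int((labels[m] == 0).sum())
        out["strata"][str(name)] = met
    return out


def append_clinical(X: np.ndarray, clinical: pd.DataFrame,
                    variables=CLINICAL_VARIABLES,
                    train_idx: np.ndarray | None = None):
    """Append encoded clinical columns after the image-feature columns.

    ER/PgR/HER2 are encoded 0/1 and subtype as a single 3-level code
    (Luminal 0, HER2+ 1, Triple Negative 2). Missing values are imputed to
    the training-fold mode; imputed (row, variable) pairs are returned in
    the info dict. ``X`` may have zero columns (clinical-only model).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) != len(clinical):
        raise ValueError("X and clinical table must align row-wise")
    train_idx = np.arange(len(clinical)) if train_idx is None else np.asarray(train_idx)
    cols = []
    imputed = []
    for var in variables:
        if var not in clinical.columns:
            raise ValueError(f"clinical variable {var!r} missing from table")
        raw = clinical[var]
        if var == "subtype":
            enc = raw.map(lambda v: SUBTYPE_CODES.get(v, np.nan) if pd.notna(v) else np.nan)
            bad = raw.notna() & enc.isna()
            if bad.any():
                raise ValueError(f"unknown subtype categories: {sorted(raw[bad].unique())}")
        else:
            enc = pd.to_numeric(raw, errors="coerce")
            known = enc.dropna().unique()
            if not set(known).issubset({0, 1}):
                raise ValueError(f"variable {var!r} must be binary 0/1, got {sorted(known)}")
        enc = enc.astype(float).to_numpy()
        if np.isnan(enc[train_idx]).all():
            raise ValueError(f"variable {var!r} entirely missing in training fold")
        mode = pd.Series(enc[train_idx]).dropna().mode().iloc[0]
        miss = np.flatnonzero(np.isnan(enc))
        for i in miss:
            imputed.append((int(i), var))
        enc[miss] = mode
        cols.append(enc)
    augmented = np.column_stack([X] + cols) if cols else X
    return augmented, {"imputed": imputed, "n_clinical": len(cols)}
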