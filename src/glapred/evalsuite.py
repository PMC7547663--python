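"""Evaluation metrics and validation protocols.

Four protocols are provided: a stratified 80/20 independent set test,
self-consistency (train and test on the same data), stratified k-fold
cross-validation (default k = 10, fold-averaged metrics), and the jackknife
(leave-one-out, pooled confusion matrix). Inside every protocol the feature
scaler is fitted on the training portion only.

Metrics are sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy Acc = (TP+TN)/total and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC
defined as 0 when any denominator factor vanishes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split

from .classify import ModelConfig, predict, predict_score, train
from .featurize import apply_scaler, fit_scaler

logger = logging.getLogger(__name__)

PROTOCOLS = ("independent", "self_consistency", "kfold", "jackknife")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """2x2 confusion counts for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    tn, fp, fn, tp = _sk_confusion(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionMatrix(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn))


def metrics(cm: ConfusionMatrix) -> tuple[float | None, float | None, float, float]:
    """(Sn, Sp, Acc, MCC) from confusion counts.

    Sn (or Sp) is None with a logged warning when its denominator is zero;
    MCC is 0 when any of its four denominator factors is zero.
    """
    if cm.total < 1:
        raise ValueError("confusion matrix holds no samples")
    sn = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN > 0 else None
    if sn is None:
        logger.warning("no positive samples: sensitivity undefined")
    sp = cm.TN / (cm.TN + cm.FP) if cm.TN + cm.FP > 0 else None
    if sp is None:
        logger.warning("no negative samples: specificity undefined")
    acc = (cm.TP + cm.TN) / cm.total
    denom = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if denom == 0:
        logger.info("degenerate confusion matrix: MCC reported as 0")
        mcc = 0.0
    else:
        mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / math.sqrt(denom)
    return sn, sp, acc, mcc


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve (rank statistic over all thresholds)."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes present in y_true")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def f1(cm: ConfusionMatrix) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 if no predicted or actual positives."""
    denom = 2 * cm.TP + cm.FP + cm.FN
    return 2 * cm.TP / denom if denom > 0 else 0.0


@dataclass
class EvaluationReport:
    """Confusion counts and derived metrics for one protocol run."""

    protocol: str
    model_kind: str
    confusion: ConfusionMatrix
    sn: float | None
    sp: float | None
    acc: float
    mcc: float
    auc: float | None
    f1: float
    n: int
    seed: int | None = None
    per_fold: list[dict] | None = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv_row(self) -> pd.DataFrame:
        """One flat row per protocol x model, for Table-style tabulation."""
        d = self.to_dict()
        d.pop("per_fold")
        cmd = d.pop("confusion")
        d.update(cmd)
        return pd.DataFrame([d])


def _evaluate_split(
    X_train, y_train, X_test, y_test, model_config, scaler_mode
) -> tuple[ConfusionMatrix, np.ndarray, np.ndarray]:
    scaler = fit_scaler(X_train, mode=scaler_mode)
    model = train(apply_scaler(scaler, X_train), y_train, model_config)
    X_test_s = apply_scaler(scaler, X_test)
    y_pred = predict(model, X_test_s)
    scores = predict_score(model, X_test_s)
    return confusion(y_test, y_pred), y_pred, scores


def _report(protocol, model_config, cm, y_true, scores, seed=None, per_fold=None) -> EvaluationReport:
    sn, sp, acc, mcc = metrics(cm)
    auc = roc_auc(y_true, scores) if len(np.unique(y_true)) == 2 else None
    return EvaluationReport(
        protocol=protocol,
        model_kind=model_config.kind,
        confusion=cm,
        sn=sn,
        sp=sp,
        acc=acc,
        mcc=mcc,
        auc=auc,
        f1=f1(cm),
        n=cm.total,
        seed=seed,
        per_fold=per_fold,
    )


def independent_test(
    X,
    y,
    model_config: ModelConfig | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
    scaler_mode: str = "standard",
) -> EvaluationReport:
    """Single stratified shuffled split: fit on 80%, evaluate on held-out 20%."""
    model_config = model_config or ModelConfig()
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y, shuffle=True
    )
    cm, _, scores = _evaluate_split(X_tr, y_tr, X_te, y_te, model_config, scaler_mode)
    return _report("independent", model_config, cm, y_te, scores, seed=seed)


def self_consistency_test(
    X, y, model_config: ModelConfig | None = None, scaler_mode: str = "standard"
) -> EvaluationReport:
    """Train and evaluate on the identical full dataset (optimistic bias)."""
    model_config = model_config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cm, _, scores = _evaluate_split(X, y, X, y, model_config, scaler_mode)
    return _report("self_consistency", model_config, cm, y, scores, seed=model_config.random_seed)


def kfold_test(
    X,
    y,
    model_config: ModelConfig | None = None,
    k: int = 10,
    seed: int = 0,
    scaler_mode: str = "standard",
) -> EvaluationReport:
    """Stratified k-fold cross-validation with fold-averaged metrics.

    The report's headline Sn/Sp/Acc/MCC are unweighted means over folds; the
    confusion matrix and AUC are pooled over all held-out predictions. With
    k equal to the sample count the partition degrades to leave-one-out
    (single-sample folds cannot be stratified), making the pooled result
    identical to the jackknife for a deterministic model.
    """
    model_config = model_config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count n={n}")
    if k == n:
        splits = LeaveOneOut().split(X, y)
    else:
        splits = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed).split(X, y)

    per_fold = []
    pooled_true, pooled_pred, pooled_scores = [], [], []
    for fold_idx, (tr, te) in enumerate(splits):
        cm, y_pred, scores = _evaluate_split(
            X[tr], y[tr], X[te], y[te], model_config, scaler_mode
        )
        sn, sp, acc, mcc = metrics(cm)
        per_fold.append(
            {
                "fold": fold_idx,
                "n": int(cm.total),
                "sn": sn,
                "sp": sp,
                "acc": acc,
                "mcc": mcc,
                "confusion": dataclasses.asdict(cm),
            }
        )
        pooled_true.append(y[te])
        pooled_pred.append(y_pred)
        pooled_scores.append(scores)

    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    scores = np.concatenate(pooled_scores)
    pooled_cm = confusion(y_true, y_pred)

    def _fold_mean(key):
        vals = [f[key] for f in per_fold if f[key] is not None]
        return float(np.mean(vals)) if vals else None

    auc = roc_auc(y_true, scores) if len(np.unique(y_true)) == 2 else None
    return EvaluationReport(
        protocol="kfold",
        model_kind=model_config.kind,
        confusion=pooled_cm,
        sn=_fold_mean("sn"),
        sp=_fold_mean("sp"),
        acc=_fold_mean("acc"),
        mcc=_fold_mean("mcc"),
        auc=auc,
        f1=f1(pooled_cm),
        n=pooled_cm.total,
        seed=seed,
        per_fold=per_fold,
    )


def jackknife_test(
    X, y, model_config: ModelConfig | None = None, scaler_mode: str = "standard"
) -> EvaluationReport:
    """Leave-one-out: n model fits, one pooled confusion matrix."""
    model_config = model_config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < 2:
        raise ValueError("jackknife needs at least two samples")
    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    for tr, te in LeaveOneOut().split(X, y):
        scaler = fit_scaler(X[tr], mode=scaler_mode)
        model = train(apply_scaler(scaler, X[tr]), y[tr], model_config)
        X_te = apply_scaler(scaler, X[te])
        preds[te[0]] = predict(model, X_te)[0]
        scores[te[0]] = predict_score(model, X_te)[0]
    cm = confusion(y, preds)
    return _report(
        "jackknife", model_config, cm, y, scores, seed=model_config.random_seed
    )


def run_protocol(
    protocol: str,
    X,
    y,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    k: int = 10,
    test_fraction: float = 0.2,
    scaler_mode: str = "standard",
) -> EvaluationReport:
    """Dispatch to one of the four validation protocols by name."""
    if protocol == "independent":
        return independent_test(X, y, model_config, test_fraction, seed, scaler_mode)
    if protocol == "self_consistency":
        return self_consistency_test(X, y, model_config, scaler_mode)
    if protocol == "kfold":
        return kfold_test(X, y, model_config, k, seed, scaler_mode)
    if protocol == "jackknife":
        return jackknife_test(X, y, model_config, scaler_mode)
    raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
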