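"""GBDT training, grid-searched five-fold CV, prediction, and evaluation.

The classifier is a gradient-boosted ensemble of CART regression trees fit
by forward stagewise additive boosting. Model selection searches only the
three parameters that matter most for this family — number of trees, tree
depth, and learning rate — by mean held-out AUC over stratified folds.

Evaluation metrics from the confusion matrix:

    Acc = (TP+TN)/(TP+FP+TN+FN)        Sen = TP/(TP+FN)
    Pre = TP/(TP+FP)                   F1  = 2*Pre*Sen/(Pre+Sen)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Any zero factor in MCC's denominator yields MCC = 0 by convention; the
degenerate ratios (Sen, Pre, F1 with empty denominators) are also 0.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoders import ScalerParams, minmax_apply
from .selection import SelectionResult, apply_selection

#: Default grid; contains the reference operating point (200 trees, depth 6, lr 1.0).
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [50, 100, 200, 400],
    "max_depth": [3, 6, 9],
    "learning_rate": [0.1, 0.5, 1.0],
}


@dataclass(frozen=True)
class GbdtParams:
    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1 or self.learning_rate <= 0:
            raise ValueError(f"invalid GBDT parameters: {self}")


def train_gbdt(X: np.ndarray, y: np.ndarray, params: GbdtParams) -> GradientBoostingClassifier:
    """Fit the boosted-tree classifier; deterministic given params.seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = GradientBoostingClassifier(
        n_estimators=params.n_estimators,
        max_depth=params.max_depth,
        learning_rate=params.learning_rate,
        random_state=params.seed,
    )
    model.fit(X, y)
    return model


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[GbdtParams, pd.DataFrame]:
    """Exhaustive search over the parameter grid by mean held-out-fold AUC.

    Folds are stratified; every combination is refit ``folds`` times. Ties
    on mean AUC prefer fewer trees, then shallower trees, then smaller
    learning rate. Returns the winning parameters and the full results table.
    """
    grid = dict(grid or DEFAULT_GRID)
    combos = list(
        itertools.product(
            grid.get("n_estimators", [200]),
            grid.get("max_depth", [6]),
            grid.get("learning_rate", [1.0]),
        )
    )
    if not combos:
        raise ValueError("empty parameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    rows = []
    for n_est, depth, lr in combos:
        params = GbdtParams(n_est, depth, lr, seed)
        aucs, accs = [], []
        for train_idx, test_idx in splits:
            if len(np.unique(y[test_idx])) < 2:
                raise ValueError("a CV fold contains a single class; use fewer folds")
            model = train_gbdt(X[train_idx], y[train_idx], params)
            proba = model.predict_proba(X[test_idx])[:, 1]
            aucs.append(roc_auc(y[test_idx], proba))
            accs.append(float(np.mean((proba >= 0.5).astype(int) == y[test_idx])))
        rows.append(
            {
                "n_estimators": n_est,
                "max_depth": depth,
                "learning_rate": lr,
                "mean_auc": float(np.mean(aucs)),
                "std_auc": float(np.std(aucs)),
                "mean_acc": float(np.mean(accs)),
            }
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_auc", "n_estimators", "max_depth", "learning_rate"],
        ascending=[False, True, True, True],
        kind="stable",
    ).iloc[0]
    return (
        GbdtParams(int(best.n_estimators), int(best.max_depth), float(best.learning_rate), seed),
        table,
    )


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for binary vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


@dataclass
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    Acc: float
    Sen: float
    Pre: float
    F1: float
    MCC: float
    AUC: float = float("nan")
    per_fold: list["MetricsReport"] | None = None

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    def as_dict(self) -> dict:
        return asdict(self)


def metrics(conf: tuple[int, int, int, int], auc: float = float("nan")) -> MetricsReport:
    """Evaluate Acc/Sen/Pre/F1/MCC from confusion counts."""
    tp, fp, tn, fn = conf
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = ((tp * tn) - (fp * fn)) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(tp, fp, tn, fn, acc, sen, pre, float(f1), float(mcc), auc)


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (= normalized Mann-Whitney U; ties count 1/2)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y_true, scores))


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(y_true, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def evaluate_predictions(
    y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Threshold probabilities (>= maps to positive) and compute all metrics."""
    y_pred = (np.asarray(proba) >= threshold).astype(int)
    report = metrics(confusion(y_true, y_pred))
    report.AUC = roc_auc(y_true, proba)
    return report


@dataclass
class ModelBundle:
    """End-to-end predictor: scaler -> feature selection -> GBDT -> threshold.

    All three preprocessing artifacts must have been fitted on the same
    training partition.
    """

    scaler: ScalerParams
    selection: SelectionResult
    params: GbdtParams
    model: GradientBoostingClassifier
    threshold: float = 0.5

    def predict(self, raw_feature_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return predict(self, raw_feature_rows)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a ModelBundle")
        return bundle


def predict(bundle: ModelBundle, raw_feature_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply scaler, then selection, then the model, then the threshold.

    Returns (positive-class probabilities, hard labels); probability exactly
    at the threshold maps to the positive class.
    """
    X = np.asarray(raw_feature_rows, dtype=float)
    X = minmax_apply(X, bundle.scaler)
    X = apply_selection(X, bundle.selection)
    proba = bundle.model.predict_proba(X)[:, 1]
    return proba, (proba >= bundle.threshold).astype(int)
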