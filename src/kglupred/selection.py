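"""Elastic-Net feature selection.

A linear model of the binary label on the normalized feature matrix is fit
with a combined L1/L2 penalty; coordinate descent drives redundant
coefficients to exact zero, and the surviving columns are the selected
features. "Nonzero" means exactly nonzero as returned by the solver — no
epsilon threshold — because the L1 term produces exact zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet


@dataclass
class SelectionResult:
    alpha: float
    l1_ratio: float
    selected_indices: np.ndarray
    coefficient_magnitudes: np.ndarray
    column_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        self.coefficient_magnitudes = np.asarray(self.coefficient_magnitudes, dtype=float)
        if len(self.selected_indices) and (
            np.any(np.diff(self.selected_indices) <= 0)
            or self.selected_indices[0] < 0
            or self.selected_indices[-1] >= len(self.coefficient_magnitudes)
        ):
            raise ValueError("selected_indices must be strictly increasing and in range")

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha": self.alpha,
                    "l1_ratio": self.l1_ratio,
                    "selected_indices": self.selected_indices.tolist(),
                    "coefficient_magnitudes": self.coefficient_magnitudes.tolist(),
                    "column_labels": self.column_labels,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            d["alpha"],
            d["l1_ratio"],
            np.array(d["selected_indices"], dtype=int),
            np.array(d["coefficient_magnitudes"]),
            d.get("column_labels"),
        )


def elasticnet_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 1e-6,
    l1_ratio: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int = 0,
    column_labels: Sequence[str] | None = None,
) -> SelectionResult:
    """Fit the penalized linear regression of y on X and keep |coef| > 0.

    The default alpha of 1e-6 is a nearly unpenalized fit that prunes only
    genuinely redundant columns. Deterministic given seed and tolerances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in X")
    if np.all(y == y[0]):
        raise ValueError("y is constant; nothing to regress on")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    model = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, tol=tol, max_iter=max_iter, random_state=seed
    )
    with warnings.catch_warnings():
        # tiny alphas legitimately stop on max_iter; the support is stable
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    coefs = np.abs(model.coef_)
    selected = np.flatnonzero(coefs > 0)
    return SelectionResult(
        alpha,
        l1_ratio,
        selected,
        coefs,
        list(column_labels) if column_labels is not None else None,
    )


def apply_selection(X: np.ndarray, result: SelectionResult) -> np.ndarray:
    """Filter X down to the selected columns (order-preserving)."""
    X = np.asarray(X)
    if X.shape[1] != len(result.coefficient_magnitudes):
        raise ValueError(
            f"X has {X.shape[1]} columns, selection was fitted on "
            f"{len(result.coefficient_magnitudes)}"
        )
    if result.n_selected == 0:
        raise ValueError("selection is empty; refusing to emit a 0-column matrix")
    return X[:, result.selected_indices]


def selected_labels(result: SelectionResult) -> list[str]:
    if result.column_labels is None:
        raise ValueError("selection carries no column labels")
    return [result.column_labels[i] for i in result.selected_indices]


def alpha_sweep(
    X: np.ndarray,
    y: np.ndarray,
    alphas: Iterable[float],
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    l1_ratio: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One (alpha, n_selected, downstream score) row per alpha.

    Each row is an independent fit (no model caching); ``evaluator`` maps the
    reduced matrix and labels to a downstream figure of merit such as
    cross-validated AUC.
    """
    alphas = list(alphas)
    if not alphas:
        raise ValueError("at least one alpha required")
    rows = []
    for a in alphas:
        result = elasticnet_select(
            X, y, alpha=a, l1_ratio=l1_ratio, tol=tol, max_iter=max_iter, seed=seed
        )
        score = (
            evaluator(apply_selection(X, result), y) if result.n_selected else float("nan")
        )
        rows.append({"alpha": a, "n_selected": result.n_selected, "score": score})
    return pd.DataFrame(rows)
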