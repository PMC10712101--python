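"""End-to-end orchestration: encode -> normalize -> balance -> select -> GBDT.

The training flow mirrors the intended use on real data: windows are cut
from proteins, split into training and independent test partitions, the
scaler/balancer/selector/model are all fitted on the training partition
only, and the independent test set is touched once, at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data_io
from .data_io import DatasetSplit, PeptideWindow
from .encoders import FeatureMatrix, encode_windows, minmax_apply, minmax_fit
from .imbalance import SamplerConfig, balance_training
from .model import (
    GbdtParams,
    MetricsReport,
    ModelBundle,
    evaluate_predictions,
    grid_search_cv,
    train_gbdt,
)
from .selection import elasticnet_select
from .synthetic import MotifSpec, SyntheticDataset, generate_peptolome

#: Compact search grid for corpus-scale runs on a single CPU; it brackets
#: the reference operating point (200 trees, depth 6, learning rate 1.0).
STUDY_GRID: dict[str, list] = {
    "n_estimators": [100, 200],
    "max_depth": [3, 6],
    "learning_rate": [1.0],
}


@dataclass
class PipelineResult:
    bundle: ModelBundle
    report: MetricsReport
    cv_table: pd.DataFrame
    split: DatasetSplit
    n_features_in: int
    n_features_selected: int
    n_balanced: int


def dataset_windows(dataset: SyntheticDataset, flank: int = 16) -> list[PeptideWindow]:
    return data_io.extract_windows(dataset.proteins, dataset.annotations, flank)


def fit_pipeline(
    train_features: FeatureMatrix,
    sampler: SamplerConfig | None = None,
    alpha: float = 1e-6,
    l1_ratio: float = 0.5,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[ModelBundle, pd.DataFrame, int]:
    """Fit scaler, balancer, selector and grid-searched GBDT on training rows.

    Returns the bundle, the grid-search table and the balanced row count.
    """
    sampler = sampler or SamplerConfig(seed=seed)
    X_raw = train_features.values
    y = train_features.labels
    scaler = minmax_fit(X_raw)
    X = minmax_apply(X_raw, scaler)
    kept = balance_training(X, y, sampler)
    Xb, yb = X[kept], y[kept]
    selection = elasticnet_select(
        Xb, yb, alpha=alpha, l1_ratio=l1_ratio, seed=seed,
        column_labels=train_features.column_labels,
    )
    Xs = Xb[:, selection.selected_indices]
    best, cv_table = grid_search_cv(Xs, yb, grid=grid, folds=folds, seed=seed)
    model = train_gbdt(Xs, yb, best)
    bundle = ModelBundle(scaler, selection, best, model, threshold)
    return bundle, cv_table, len(kept)


def run_pipeline(
    dataset: SyntheticDataset,
    test_fraction: float = 0.25,
    sampler: SamplerConfig | None = None,
    alpha: float = 1e-6,
    l1_ratio: float = 0.5,
    grid: Mapping[str, Sequence] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> PipelineResult:
    """The full study flow on one dataset; returns the independent-test report."""
    windows = dataset_windows(dataset)
    split = data_io.split_dataset(windows, test_fraction, stratified=True, seed=seed)
    train_fm = encode_windows(split.train, pssms=dataset.pssms, ss=dataset.ss)
    test_fm = encode_windows(split.test, pssms=dataset.pssms, ss=dataset.ss)
    bundle, cv_table, n_balanced = fit_pipeline(
        train_fm, sampler=sampler or SamplerConfig(seed=seed),
        alpha=alpha, l1_ratio=l1_ratio, grid=grid, folds=folds, seed=seed,
    )
    proba, _ = bundle.predict(test_fm.values)
    report = evaluate_predictions(test_fm.labels, proba, bundle.threshold)
    return PipelineResult(
        bundle=bundle,
        report=report,
        cv_table=cv_table,
        split=split,
        n_features_in=train_fm.values.shape[1],
        n_features_selected=bundle.selection.n_selected,
        n_balanced=n_balanced,
    )


def run_synthetic_pipeline(
    n_pos: int = 530,
    n_neg: int = 3277,
    spec: MotifSpec | None = None,
    **kwargs,
) -> PipelineResult:
    """Generate a synthetic corpus and run the full pipeline on it."""
    dataset = generate_peptolome(n_pos, n_neg, spec)
    return run_pipeline(dataset, **kwargs)
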