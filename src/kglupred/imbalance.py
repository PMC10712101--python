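"""Majority-class down-sampling: NearMiss-1/2/3 and random under-sampling.

All samplers return indices INTO THE MAJORITY SET of the rows to retain;
minority rows are never modified or dropped. Distances are Euclidean and
are meant to be computed on the min-max-normalized feature matrix. Ties in
every ranking are broken by ascending original index, so results are
deterministic and permutation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances

METHODS = ("nearmiss1", "nearmiss2", "nearmiss3", "random")


@dataclass(frozen=True)
class SamplerConfig:
    method: str = "nearmiss3"
    k_neighbors: int = 3
    target_ratio: float = 1.0  # minority : majority after sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def _check(majority_rows: np.ndarray, minority_rows: np.ndarray, k: int, n_keep: int):
    maj = np.atleast_2d(np.asarray(majority_rows, dtype=float))
    mino = np.atleast_2d(np.asarray(minority_rows, dtype=float))
    if maj.shape[0] == 0 or mino.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if k > mino.shape[0]:
        raise ValueError(f"k={k} exceeds minority size {mino.shape[0]}")
    if n_keep > maj.shape[0]:
        raise ValueError(f"n_keep={n_keep} exceeds majority size {maj.shape[0]}")
    return maj, mino


def _take_smallest(scores: np.ndarray, n_keep: int) -> np.ndarray:
    """Indices of the n_keep smallest scores, ties by ascending index."""
    order = np.argsort(scores, kind="stable")
    return np.sort(order[:n_keep])


def nearmiss1(
    majority_rows: np.ndarray, minority_rows: np.ndarray, k: int = 3, n_keep: int | None = None
) -> np.ndarray:
    """Keep majority rows with the smallest mean distance to their k NEAREST
    minority neighbours."""
    maj, mino = _check(majority_rows, minority_rows, k, n_keep or 0)
    if n_keep is None:
        n_keep = mino.shape[0]
    d = np.sort(pairwise_distances(maj, mino), axis=1)
    scores = d[:, :k].mean(axis=1)
    return _take_smallest(scores, n_keep)


def nearmiss2(
    majority_rows: np.ndarray, minority_rows: np.ndarray, k: int = 3, n_keep: int | None = None
) -> np.ndarray:
    """Keep majority rows with the smallest mean distance to their k FARTHEST
    minority neighbours."""
    maj, mino = _check(majority_rows, minority_rows, k, n_keep or 0)
    if n_keep is None:
        n_keep = mino.shape[0]
    d = np.sort(pairwise_distances(maj, mino), axis=1)
    scores = d[:, -k:].mean(axis=1)
    return _take_smallest(scores, n_keep)


def nearmiss3(
    majority_rows: np.ndarray, minority_rows: np.ndarray, k: int = 3, n_keep: int | None = None
) -> np.ndarray:
    """Two-phase rule: every minority row nominates its k nearest majority
    rows as candidates (so each minority point keeps majority context);
    candidates are then ranked by mean distance to their k nearest minority
    neighbours, LARGEST first, and the top n_keep are retained. If the
    candidate union is smaller than n_keep, non-candidates are appended
    under the same ranking.
    """
    maj, mino = _check(majority_rows, minority_rows, k, n_keep or 0)
    if n_keep is None:
        n_keep = mino.shape[0]
    d = pairwise_distances(maj, mino)  # majority x minority
    k_cand = min(k, maj.shape[0])
    nominate = np.argsort(d.T, axis=1, kind="stable")[:, :k_cand]  # minority x k
    candidates = np.unique(nominate)
    d_sorted = np.sort(d, axis=1)
    scores = d_sorted[:, :k].mean(axis=1)
    # descending score, ascending index on ties
    rank = np.lexsort((np.arange(maj.shape[0]), -scores))
    cand_set = set(candidates.tolist())
    ranked_cand = [i for i in rank if i in cand_set]
    ranked_rest = [i for i in rank if i not in cand_set]
    keep = (ranked_cand + ranked_rest)[:n_keep]
    return np.sort(np.array(keep, dtype=int))


def random_undersample(
    majority_rows: np.ndarray, n_keep: int, seed: int = 0
) -> np.ndarray:
    """Uniform sample without replacement of n_keep majority indices."""
    maj = np.atleast_2d(np.asarray(majority_rows))
    if n_keep > maj.shape[0]:
        raise ValueError(f"n_keep={n_keep} exceeds majority size {maj.shape[0]}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(maj.shape[0], size=n_keep, replace=False))


def balance_training(
    X: np.ndarray, y: np.ndarray, config: SamplerConfig
) -> np.ndarray:
    """Down-sample the majority class of (X, y); returns retained ROW indices
    into X (all minority rows plus the selected majority rows, in original
    order). The minority class is the rarer label.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ValueError("balance_training expects exactly two classes")
    minority_label = values[np.argmin(counts)]
    min_idx = np.flatnonzero(y == minority_label)
    maj_idx = np.flatnonzero(y != minority_label)
    n_keep = min(len(maj_idx), int(round(len(min_idx) / config.target_ratio)))
    if config.method == "random":
        kept = random_undersample(X[maj_idx], n_keep, config.seed)
    else:
        fn = {"nearmiss1": nearmiss1, "nearmiss2": nearmiss2, "nearmiss3": nearmiss3}[
            config.method
        ]
        kept = fn(X[maj_idx], X[min_idx], config.k_neighbors, n_keep)
    return np.sort(np.concatenate([min_idx, maj_idx[kept]]))
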