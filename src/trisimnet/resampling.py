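"""Class rebalancing: SMOTE oversampling and combined over/under-sampling.

SMOTE synthesizes a minority-class sample by picking a minority row x_i,
one of its k nearest same-class neighbours x_nn (Euclidean), and a uniform
u in [0, 1], and emitting the convex combination ``x_i + u * (x_nn - x_i)``.
Original rows are always preserved; only new rows are appended.

The combined scheme used for the ED-acuity cohort SMOTEs classes below the
median class size up to the median and randomly undersamples classes above
it down to the median (both seeded).
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["BalanceError", "smote", "smote_undersample"]


class BalanceError(ValueError):
    """A class is too small for the requested resampling."""


def _class_counts(y: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(y, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def _check_min_size(counts: dict[int, int], k_neighbors: int) -> None:
    for cls, cnt in counts.items():
        if cnt < k_neighbors + 1:
            raise BalanceError(
                f"class {cls} has {cnt} members; SMOTE with k={k_neighbors} "
                f"needs at least {k_neighbors + 1}"
            )


def _synthesize(
    X_cls: np.ndarray, n_new: int, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate ``n_new`` interpolated rows within one class."""
    if n_new <= 0:
        return np.empty((0, X_cls.shape[1]))
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_cls)
    # Drop the first neighbour (the point itself).
    nbr_idx = nn.kneighbors(X_cls, return_distance=False)[:, 1:]
    seeds = rng.integers(0, len(X_cls), size=n_new)
    chosen = nbr_idx[seeds, rng.integers(0, k_neighbors, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=(n_new, 1))
    return X_cls[seeds] + u * (X_cls[chosen] - X_cls[seeds])


def _oversample_to(
    X: np.ndarray,
    y: np.ndarray,
    targets: dict[int, int],
    k_neighbors: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    parts_X, parts_y = [X], [y]
    for cls in sorted(targets):
        mask = y == cls
        n_new = targets[cls] - int(mask.sum())
        if n_new > 0:
            synth = _synthesize(X[mask], n_new, k_neighbors, rng)
            parts_X.append(synth)
            parts_y.append(np.full(n_new, cls, dtype=y.dtype))
    return np.concatenate(parts_X), np.concatenate(parts_y)


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    ratio: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes up to ``ratio`` times the majority count.

    With ``ratio=1.0`` (the default) all classes are equalized to the
    majority count.  Original rows come first in the output, synthetic rows
    are appended; the result is deterministic under ``seed``.
    """
    if not 0.0 < ratio <= 1.0:
        raise BalanceError(f"ratio must be in (0, 1], got {ratio}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = _class_counts(y)
    _check_min_size(counts, k_neighbors)
    majority = max(counts.values())
    target = int(round(ratio * majority))
    rng = np.random.default_rng(seed)
    targets = {cls: max(cnt, target) for cls, cnt in counts.items()}
    return _oversample_to(X, y, targets, k_neighbors, rng)


def smote_undersample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined resampling: SMOTE up to the median class size, random
    undersampling down to it.  Classes at the median are untouched."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = _class_counts(y)
    _check_min_size(counts, k_neighbors)
    median = int(np.median(list(counts.values())))
    rng = np.random.default_rng(seed)
    keep = np.ones(len(y), dtype=bool)
    for cls in sorted(counts):
        cnt = counts[cls]
        if cnt > median:
            idx = np.flatnonzero(y == cls)
            drop = rng.choice(idx, size=cnt - median, replace=False)
            keep[drop] = False
    X_kept, y_kept = X[keep], y[keep]
    targets = {cls: median for cls, cnt in counts.items() if cnt < median}
    return _oversample_to(X_kept, y_kept, targets, k_neighbors, rng)
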