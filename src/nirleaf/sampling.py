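"""Deterministic Kennard-Stone train/test partitioning.

Kennard-Stone selects a representative calibration subset by max-min
distance: seed with the globally farthest pair, then repeatedly add the
candidate whose minimum distance to the selected set is largest.  There is
no randomness anywhere; ties in either stage are broken by the lowest row
index, so identical inputs give identical splits on any platform.

Split sizes follow round-half-up of ``fraction * n``, the convention that
reproduces the study design's 70/30 splits of 1128/1085/1141 samples as
790/760/799.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError

__all__ = ["train_size", "kennard_stone", "split_dataset", "SplitResult"]


def train_size(n: int, fraction: float) -> int:
    """Round-half-up of ``fraction * n``; the complement goes to test.

    Uses decimal arithmetic on the printed value of ``fraction`` so that
    exact halves (e.g. 0.7 of 1085 = 759.5) round up rather than being lost
    to binary floating point.
    """
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    if not (0 < fraction < 1):
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    exact = Decimal(repr(fraction)) * Decimal(n)
    return int(exact.to_integral_value(rounding=ROUND_HALF_UP))


def kennard_stone(X, n_select: int, metric: str = "euclidean") -> np.ndarray:
    """Selection order of ``n_select`` rows by the Kennard-Stone max-min rule.

    The first two indices are a globally farthest pair (lowest-index pair on
    ties, lower index first); each subsequent pick maximizes its minimum
    distance to the already-selected set, lowest index on ties.  Returns the
    indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError(f"X must be 2-D, got shape {X.shape}")
    n = X.shape[0]
    if not (2 <= n_select <= n):
        raise ParameterError(f"n_select must be in [2, {n}], got {n_select}")

    if metric == "mahalanobis":
        cov = np.cov(X, rowvar=False)
        D = cdist(X, X, metric="mahalanobis", VI=np.linalg.pinv(np.atleast_2d(cov)))
    else:
        D = cdist(X, X, metric=metric)

    # farthest pair; np.argmax scans row-major so ties resolve to lowest (i, j)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    if D[i, j] <= 0:
        raise ParameterError("all rows coincide; Kennard-Stone is undefined")
    first, second = (int(min(i, j)), int(max(i, j)))
    selected = [first, second]
    remaining = np.ones(n, dtype=bool)
    remaining[first] = remaining[second] = False

    # min distance from each candidate to the selected set, updated per pick
    min_dist = np.minimum(D[:, first], D[:, second])
    for _ in range(n_select - 2):
        masked = np.where(remaining, min_dist, -np.inf)
        pick = int(np.argmax(masked))  # argmax returns the lowest index on ties
        selected.append(pick)
        remaining[pick] = False
        min_dist = np.minimum(min_dist, D[:, pick])
    return np.array(selected, dtype=int)


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test row indices covering the whole dataset."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float


def split_dataset(X, fraction: float = 0.7, metric: str = "euclidean") -> SplitResult:
    """Kennard-Stone split: train = KS selection of round-half-up(fraction·n).

    ``X`` is the matrix the distances are computed on — typically the
    preprocessed spectra.  Test rows are the complement, in ascending order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = train_size(n, fraction)
    train = kennard_stone(X, k, metric=metric)
    mask = np.ones(n, dtype=bool)
    mask[train] = False
    return SplitResult(
        train_indices=train,
        test_indices=np.nonzero(mask)[0],
        fraction=fraction,
    )
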