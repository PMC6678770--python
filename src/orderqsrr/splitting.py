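"""Kennard–Stone training / external-validation split.

The split is fully deterministic: descriptors are autoscaled, the two most
distant analytes seed the training set, and candidates joining it are the
ones farthest (max–min Euclidean distance) from what is already selected.
Chemometric QSRR studies use this to give the training set uniform coverage
of descriptor space, leaving the validation set interpolative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataset import RetentionDataset

__all__ = ["SplitResult", "kennard_stone_split"]


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitResult:
    train_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]
    fraction: float

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.validation_indices):
            raise SplitError("train and validation sets overlap")


def _autoscale(X: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        bad = [names[i] for i in zero]
        raise SplitError(f"descriptor column(s) with zero variance: {bad}")
    return (X - mean) / sd


def kennard_stone_split(
    ds: RetentionDataset, fraction: float = 0.70
) -> SplitResult:
    """Classic Kennard–Stone selection of ``round(fraction·n)`` training rows.

    Ties in any distance comparison are broken by the lowest row index, so
    identical inputs always yield identical splits.
    """
    if not 0 < fraction < 1:
        raise SplitError("fraction must be in (0, 1)")
    n, k = ds.n, ds.k
    if n < 4:
        raise SplitError(f"need at least 4 analytes to split, got {n}")
    # half-up rounding; np.round would round half to even
    n_train = int(np.floor(fraction * n + 0.5))
    # a split smaller than K + 2 cannot support a fit downstream, but the
    # selection itself only needs the seed pair; fitting enforces its own
    # minimum, so only the degenerate cases are rejected here
    if n_train < 2:
        raise SplitError(f"training size {n_train} < 2")
    if n_train >= n:
        raise SplitError("fraction leaves no validation analytes")

    Z = _autoscale(ds.X, ds.descriptor_names)
    dist = squareform(pdist(Z, metric="euclidean"))

    # seed: the globally most distant pair, lowest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = int(np.argmax(flat))  # argmax returns the first = lexicographic min
    selected = [int(iu[0][best]), int(iu[1][best])]

    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = dist[:, selected].min(axis=1)
    while len(selected) < n_train:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))  # first index wins ties
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, dist[:, nxt])

    train = tuple(sorted(selected))
    validation = tuple(i for i in range(n) if i not in set(train))
    return SplitResult(train, validation, fraction)
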