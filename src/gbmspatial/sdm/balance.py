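"""SMOTE balancing of the training quadrats.

Synthetic minority oversampling: each synthetic sample is a convex
combination of a real minority-class member and one of its k nearest
same-class neighbours, so every synthetic point lies on a segment between
two real points of its class.  Classes are topped up to the majority-class
count; synthetic samples are flagged and must never leave the training set.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample minority classes to the majority count.

    Returns ``(X_aug, y_aug, synthetic)`` where ``synthetic`` flags the
    generated rows (all real rows come first, in input order).  When a class
    has fewer than ``k_neighbors + 1`` members, k is reduced with a warning.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()

    new_X: list[np.ndarray] = []
    new_y: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        need = int(target - cnt)
        if need == 0:
            continue
        members = X[y == cls]
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; cannot SMOTE")
        k = k_neighbors
        if cnt < k + 1:
            k = cnt - 1
            warnings.warn(
                f"class {cls!r} has {cnt} members; reducing k_neighbors to {k}"
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
        _, nbr = nn.kneighbors(members)  # first column is self
        base = rng.integers(0, cnt, need)
        pick = nbr[base, rng.integers(1, k + 1, need)]
        lam = rng.random(need)[:, None]
        new_X.append(members[base] + lam * (members[pick] - members[base]))
        new_y.append(np.full(need, cls, dtype=y.dtype))

    if not new_X:
        return X, y, np.zeros(len(y), dtype=bool)
    X_aug = np.vstack([X] + new_X)
    y_aug = np.concatenate([y] + new_y)
    synthetic = np.concatenate(
        [np.zeros(len(y), dtype=bool), np.ones(len(X_aug) - len(y), dtype=bool)]
    )
    return X_aug, y_aug, synthetic
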