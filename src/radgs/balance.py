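"""SMOTE class balancing with per-row provenance.

Synthetic minority oversampling: each synthetic sample is drawn on the
segment between a minority sample x and one of its k nearest minority
neighbors x', as x + delta * (x' - x) with one delta ~ Uniform(0, 1) shared
across features (the classic formulation). Exactly enough synthetics are
generated to equalize class counts; originals are preserved verbatim and
every synthetic row records its two parent indices, which lets the
cross-validation driver assert that no test-fold row ever parents a
synthetic training row.

Balancing is meant to run strictly inside training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["BalancedTable", "smote"]


@dataclass
class BalancedTable:
    """Original + synthetic rows with provenance.

    ``provenance`` has one entry per row: None for originals, or a tuple
    ``(parent_a, parent_b, delta)`` of original-row indices and the
    interpolation coefficient for synthetics.
    """

    x: np.ndarray
    y: np.ndarray
    provenance: list[tuple[int, int, float] | None]

    @property
    def n_synthetic(self) -> int:
        return sum(p is not None for p in self.provenance)


def smote(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> BalancedTable:
    """Oversample every non-majority class up to the majority count.

    Parameters use SMOTE's canonical defaults (k = 5 Euclidean neighbors);
    k is reduced with a warning when a minority class has n <= k, and a
    singleton minority class is an error since it has no neighbor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = int(counts.max())

    new_rows: list[np.ndarray] = []
    new_labels: list = []
    provenance: list[tuple[int, int, float] | None] = [None] * len(y)
    for cls, cnt in zip(classes, counts):
        need = target - int(cnt)
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(f"class {cls!r} has a single sample; SMOTE needs a neighbor")
        k_eff = min(k, int(cnt) - 1)
        if k_eff < k:
            warnings.warn(
                f"class {cls!r}: k reduced from {k} to {k_eff} (n={cnt})", stacklevel=2
            )
        idx = np.nonzero(y == cls)[0]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x[idx])
        _, neigh = nn.kneighbors(x[idx])  # first neighbor is the point itself
        for _ in range(need):
            a = int(rng.integers(cnt))
            b = int(neigh[a][1 + rng.integers(k_eff)])
            delta = float(rng.uniform())
            new_rows.append(x[idx[a]] + delta * (x[idx[b]] - x[idx[a]]))
            new_labels.append(cls)
            provenance.append((int(idx[a]), int(idx[b]), delta))

    if not new_rows:
        return BalancedTable(x.copy(), y.copy(), provenance)
    return BalancedTable(
        np.vstack([x, np.asarray(new_rows)]),
        np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)]),
        provenance,
    )
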