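"""Feature selection and univariate statistics.

ReliefF scores each feature by how well it separates nearby samples of
different classes: for every sample the k nearest same-class neighbors
(hits) and k nearest neighbors of each other class (misses) are found, and
the feature weight accumulates miss differences (prior-weighted) minus hit
differences. Features are range-normalized to [0, 1] internally so weights
land in [-1, 1]. The pass is deterministic: every sample is visited and
neighbor ties are broken by the lowest sample index.

The retention rule keeps features with strictly positive weight, ordered by
descending weight. A one-way ANOVA screen over the three Gleason groups and
Welch two-tailed t-test summaries for the binary contrasts are provided
alongside; the ANOVA screen is reported but does not gate the binary-task
feature sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import f_oneway, ttest_ind

__all__ = [
    "WeightVector",
    "SelectionResult",
    "relieff",
    "select_positive",
    "anova_screen",
    "ttest_summary",
]


@dataclass
class WeightVector:
    """ReliefF relevance weight per feature."""

    weights: dict[str, float]
    k_neighbors: int
    n_sample_iterations: int


@dataclass
class SelectionResult:
    """Features retained by a selection rule, most relevant first."""

    kept: list[str]
    rule: str


def _as_matrix(table: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(table.columns)
    x = np.asarray(table, dtype=float)
    return x, [f"f{i}" for i in range(x.shape[1])]


def _k_nearest(order_pool: np.ndarray, dists: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances in the pool, ties by lowest index."""
    order = np.lexsort((order_pool, dists[order_pool]))
    return order_pool[order][:k]


def relieff(
    table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    normalize: bool = True,
) -> WeightVector:
    """Multi-class ReliefF weights over a full deterministic pass.

    ``k`` nearest hits and misses are used per sample; for a class with
    fewer than k + 1 members k is reduced for that class (with a warning).
    Distances are Manhattan on the normalized features. Constant features
    receive weight exactly 0.
    """
    x, names = _as_matrix(table)
    y = np.asarray(labels)
    n, nf = x.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least 2 classes")
    if np.any(counts < min(k + 1, 2)):
        raise ValueError("every class needs at least 2 members")
    if np.any(counts < k + 1):
        warnings.warn(
            "some classes have fewer than k+1 samples; k reduced for those classes",
            stacklevel=2,
        )
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    if normalize:
        lo = x.min(axis=0)
        rng = x.max(axis=0) - lo
        xn = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    else:
        xn = x
    dmat = cdist(xn, xn, metric="cityblock")

    w = np.zeros(nf)
    idx_by_class = {c: np.nonzero(y == c)[0] for c in classes}
    for i in range(n):
        ci = y[i]
        hit_pool = idx_by_class[ci][idx_by_class[ci] != i]
        k_hit = min(k, hit_pool.size)
        hits = _k_nearest(hit_pool, dmat[i], k_hit)
        w -= np.abs(xn[hits] - xn[i]).sum(axis=0) / (n * k_hit)
        for c in classes:
            if c == ci:
                continue
            miss_pool = idx_by_class[c]
            k_miss = min(k, miss_pool.size)
            misses = _k_nearest(miss_pool, dmat[i], k_miss)
            scale = priors[c] / (1.0 - priors[ci])
            w += scale * np.abs(xn[misses] - xn[i]).sum(axis=0) / (n * k_miss)

    return WeightVector(dict(zip(names, w.tolist())), k_neighbors=k, n_sample_iterations=n)


def select_positive(w: WeightVector) -> SelectionResult:
    """Keep features with weight > 0, ordered by descending weight."""
    if not w.weights:
        raise ValueError("empty weight vector")
    kept = sorted(
        (name for name, wt in w.weights.items() if wt > 0),
        key=lambda name: -w.weights[name],
    )
    if not kept:
        raise ValueError(
            "no feature has positive weight; review the retention threshold"
        )
    return SelectionResult(kept=kept, rule="weight > 0, descending")


def anova_screen(
    table: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA per feature across the label groups.

    Returns a frame indexed by feature with columns ``F``, ``p`` and
    ``significant`` (p < alpha). Features that are constant within every
    group get p = 0 when group means separate and p = 1 otherwise.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    groups = [table.to_numpy(dtype=float)[y == c] for c in classes]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = f_oneway(*groups, axis=0)
    stat = np.atleast_1d(np.asarray(stat, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    # degenerate columns: zero within-group variance
    for col in np.nonzero(~np.isfinite(p))[0]:
        means = [g[:, col].mean() for g in groups]
        sds = [g[:, col].std() for g in groups]
        if max(sds) == 0.0:
            p[col] = 0.0 if (max(means) > min(means)) else 1.0
            stat[col] = np.inf if p[col] == 0.0 else 0.0
    return pd.DataFrame(
        {"F": stat, "p": p, "significant": p < alpha}, index=list(table.columns)
    )


def ttest_summary(
    table: pd.DataFrame,
    labels: np.ndarray,
    group_order: tuple | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-test (Welch by default) with group summaries.

    Returns a frame indexed by feature with columns ``mean1``, ``mean2``,
    ``sd1``, ``sd2``, ``t``, ``p`` (groups in ``group_order``, defaulting to
    sorted label order). Degenerate contrasts yield NaN p-values.
    """
    y = np.asarray(labels)
    classes = np.unique(y) if group_order is None else np.asarray(group_order)
    if classes.size != 2:
        raise ValueError("t-test summary needs exactly 2 groups")
    g1 = table.to_numpy(dtype=float)[y == classes[0]]
    g2 = table.to_numpy(dtype=float)[y == classes[1]]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("both groups need n >= 2")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = ttest_ind(g1, g2, axis=0, equal_var=equal_var)
    return pd.DataFrame(
        {
            "mean1": g1.mean(axis=0),
            "mean2": g2.mean(axis=0),
            "sd1": g1.std(axis=0, ddof=1),
            "sd2": g2.std(axis=0, ddof=1),
            "t": np.asarray(t, dtype=float),
            "p": np.asarray(p, dtype=float),
        },
        index=list(table.columns),
    )
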