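"""Masked gray-level co-occurrence texture features.

For each quantitative map the ROI values are uniformly quantized (32 levels
over the per-ROI min-max range by default) and a GLCM is accumulated for
each of the four unit-distance directions 0°, 45°, 90°, 135°. Pairs are
admitted only when BOTH pixels lie inside the (possibly inflated) ROI and
are valid in the map, and are counted symmetrically (each ordered pair and
its reverse), then normalized to a joint probability.

Six Haralick-type features are computed per direction and arithmetically
averaged over the four directions: energy, entropy (natural log), contrast,
correlation, homogeneity and the inverse difference moment (IDM). Together
with the three ROI means (ADC, ALPHE, T2) this yields the canonical
21-feature radiomic vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radgs.features import GLCM_FEATURE_NAMES, MAP_GLCM_PREFIX, MAP_MEAN_NAME
from radgs.qmaps import ParameterMap
from radgs.roi import ROIMask, masked_values

__all__ = [
    "DIRECTIONS",
    "QuantizationSpec",
    "GLCM",
    "quantize",
    "glcm",
    "glcm_features",
    "extract_features",
]

#: (dr, dc) offsets for 0°, 45°, 90°, 135° at unit distance.
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class QuantizationSpec:
    """Uniform gray-level quantization: ``levels`` bins over [lo, hi].

    With lo/hi None the per-ROI min/max is used, the convention throughout
    this package since no absolute intensity scale is shared across maps.
    """

    levels: int = 32
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.lo is not None and self.hi is not None and not (self.lo < self.hi):
            raise ValueError("lo must be < hi")


@dataclass
class GLCM:
    """A (levels x levels) co-occurrence matrix for one direction offset."""

    counts: np.ndarray
    offset: tuple[int, int]
    normalized: bool
    n_pairs: int


def quantize(grid: np.ndarray, mask: np.ndarray, spec: QuantizationSpec) -> np.ndarray:
    """Quantize map values under a mask to integer levels 1..levels.

    Returns an integer image with 0 outside the mask. Values at ``lo`` map
    to level 1 and at ``hi`` to ``levels``; a constant ROI (lo == hi) maps
    everywhere to level 1.
    """
    grid = np.asarray(grid, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("quantization mask needs at least 2 pixels")
    vals = grid[mask]
    lo = float(vals.min()) if spec.lo is None else spec.lo
    hi = float(vals.max()) if spec.hi is None else spec.hi
    out = np.zeros(grid.shape, dtype=np.int64)
    if hi <= lo:
        out[mask] = 1
        return out
    lev = 1 + np.floor((vals - lo) / (hi - lo) * spec.levels).astype(np.int64)
    out[mask] = np.clip(lev, 1, spec.levels)
    return out


def glcm(levelimg: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int) -> GLCM:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Counts ordered level pairs (p, p + offset) with both pixels inside the
    mask, adds each pair reversed, and normalizes to probabilities. If the
    direction admits no pair the zero matrix is returned un-normalized.
    """
    if offset not in DIRECTIONS:
        raise ValueError(f"offset {offset} is not a unit-distance direction")
    levelimg = np.asarray(levelimg)
    mask = np.asarray(mask, dtype=bool)
    dr, dc = offset
    h, w = levelimg.shape
    # slices selecting pixel p and its neighbor p + (dr, dc)
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    m = mask[r0, c0] & mask[r1, c1]
    i = levelimg[r0, c0][m] - 1
    j = levelimg[r1, c1][m] - 1
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)
    n_pairs = int(i.size)
    if n_pairs == 0:
        return GLCM(counts, offset, normalized=False, n_pairs=0)
    return GLCM(counts / counts.sum(), offset, normalized=True, n_pairs=n_pairs)


def glcm_features(g: GLCM) -> dict[str, float]:
    """The six texture features of a normalized GLCM.

    With p(i, j) the joint probability and mu/sigma the marginal moments:
    energy = sum p²; entropy = -sum p ln p (0 ln 0 := 0); contrast =
    sum (i-j)² p; correlation = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j),
    defined as 0 for a degenerate marginal; homogeneity = sum p/(1+|i-j|);
    IDM = sum p/(1+(i-j)²).
    """
    if not g.normalized:
        raise ValueError("glcm_features requires a normalized GLCM")
    p = g.counts
    n = p.shape[0]
    lv = np.arange(1, n + 1, dtype=float)
    ii = lv[:, None]
    jj = lv[None, :]
    diff = ii - jj
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((lv * pi).sum())
    mu_j = float((lv * pj).sum())
    var_i = float(((lv - mu_i) ** 2 * pi).sum())
    var_j = float(((lv - mu_j) ** 2 * pj).sum())
    sd = np.sqrt(var_i * var_j)
    if sd > 0:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum() / sd)
    else:
        correlation = 0.0
    nz = p > 0
    return {
        "energy": float((p**2).sum()),
        "entropy": float(-(p[nz] * np.log(p[nz])).sum()),
        "contrast": float((diff**2 * p).sum()),
        "correlation": correlation,
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "IDM": float((p / (1.0 + diff**2)).sum()),
    }


def extract_features(
    maps: dict[str, ParameterMap],
    mask: ROIMask,
    spec: QuantizationSpec | None = None,
) -> dict[str, float]:
    """The canonical 21-feature vector for one lesion at one inflation level.

    ``maps`` must provide the keys "ADC", "ALPHA" and "T2". Per map: the ROI
    mean over valid pixels, plus the six GLCM features averaged over the four
    directions (directions without any admissible pair are excluded from the
    average).
    """
    spec = spec or QuantizationSpec()
    missing = {"ADC", "ALPHA", "T2"} - set(maps)
    if missing:
        raise ValueError(f"missing maps: {sorted(missing)}")
    out: dict[str, float] = {}
    for map_name in ("ADC", "ALPHA", "T2"):
        pmap = maps[map_name]
        vals = masked_values(pmap, mask)  # raises naming the lesion if empty
        out[MAP_MEAN_NAME[map_name]] = float(vals.mean())
        roi = mask.grid & pmap.valid_mask
        levelimg = quantize(pmap.grid, roi, spec)
        per_dir = []
        for off in DIRECTIONS:
            g = glcm(levelimg, roi, off, spec.levels)
            if g.n_pairs > 0:
                per_dir.append(glcm_features(g))
        if not per_dir:
            raise ValueError(
                f"lesion {mask.lesion_id!r}: no co-occurring pixel pairs in map {map_name}"
            )
        prefix = MAP_GLCM_PREFIX[map_name]
        for feat in GLCM_FEATURE_NAMES:
            out[f"{prefix}-{feat}"] = float(np.mean([d[feat] for d in per_dir]))
    return out
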