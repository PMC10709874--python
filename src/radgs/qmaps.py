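"""Per-pixel quantitative parameter fitting for prostate mp-MRI.

Three signal models are fitted:

* DWI mono-exponential decay ``S = S0 * exp(-b * ADC)`` with b in s/mm²;
  ADC is fitted in mm²/s and reported in μm²/ms (x 10³).
* Multi-echo T2 decay ``S = S0 * exp(-TE / T2)`` with TE and T2 in ms.
* DCE empirical enhancement model on the percent signal enhancement curve,
  ``PSE(t) = A * (1 - exp(-alpha*t)) * exp(-beta*t)`` with A the enhancement
  amplitude (%), alpha the uptake rate (1/s) and beta the washout rate (1/s).

The two mono-exponentials use weighted log-linear least squares (weights S²,
which de-biases the log transform); the enhancement model uses bounded
nonlinear least squares with a deterministic multi-start fallback. Pixels
with any non-positive sample on a log-fit path are marked invalid rather
than clamped, to avoid log-domain bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SignalSeries",
    "ParameterMap",
    "EMMFit",
    "UNITS",
    "DEFAULT_BVALUES",
    "DEFAULT_ECHO_TIMES",
    "DEFAULT_DCE_SPACING",
    "fit_adc",
    "fit_t2",
    "compute_pse",
    "fit_emm",
    "fit_map",
    "um2ms_to_mm2s",
    "mm2s_to_um2ms",
]

#: Acquisition defaults (b in s/mm², TE in ms, DCE frame spacing in s).
DEFAULT_BVALUES = np.array([0.0, 50.0, 100.0, 150.0, 990.0, 1500.0])
DEFAULT_ECHO_TIMES = np.arange(30.0, 271.0, 30.0)  # 9 echoes
DEFAULT_DCE_SPACING = 8.3

UNITS = {"ADC": "um^2/ms", "T2": "ms", "ALPHA": "1/s", "A": "%", "BETA": "1/s"}

ADC_RANGE = (0.0, 10.0)  # μm²/ms
T2_RANGE = (0.0, 2000.0)  # ms, open at 0

EMM_BOUNDS = ((0.0, 0.0, 0.0), (1000.0, 10.0, 1.0))


def um2ms_to_mm2s(adc: float | np.ndarray) -> float | np.ndarray:
    """μm²/ms -> mm²/s (exact /10³)."""
    return adc / 1e3


def mm2s_to_um2ms(adc: float | np.ndarray) -> float | np.ndarray:
    """mm²/s -> μm²/ms (exact x10³)."""
    return adc * 1e3


@dataclass
class SignalSeries:
    """A per-pixel intensity series with its acquisition axis.

    ``axis_kind`` is one of ``bvalue`` (s/mm²), ``echo_time`` (ms) or
    ``time`` (s). The axis must be strictly increasing and match ``values``
    in length (>= 3).
    """

    values: np.ndarray
    axis: np.ndarray
    axis_kind: Literal["bvalue", "echo_time", "time"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.values.shape != self.axis.shape or self.values.ndim != 1:
            raise ValueError("values and axis must be 1-D of equal length")
        if self.values.size < 3:
            raise ValueError("series needs at least 3 samples")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")


@dataclass
class ParameterMap:
    """A fitted 2-D parameter grid with validity mask and fit diagnostics."""

    name: str
    grid: np.ndarray
    units: str
    valid_mask: np.ndarray
    diagnostics: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grid.shape != self.valid_mask.shape:
            raise ValueError("grid and valid_mask shapes differ")


@dataclass
class EMMFit:
    """Fitted empirical-enhancement-model parameters for one pixel."""

    A: float
    alpha: float
    beta: float
    rmse: float
    converged: bool = True

    @property
    def initial_slope(self) -> float:
        """Initial enhancement slope A*alpha in %/s (derived quantity)."""
        return self.A * self.alpha


def _weighted_loglinear(values: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Solve ln S = intercept + slope * x by least squares with weights S².

    Returns (slope, intercept); caller guarantees values > 0.
    """
    w = values**2
    y = np.log(values)
    sw = w.sum()
    sx = (w * x).sum()
    sxx = (w * x * x).sum()
    sy = (w * y).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx * sx
    if denom == 0.0:
        return 0.0, sy / sw
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / sw
    return slope, intercept


def fit_adc(series: SignalSeries) -> tuple[float, float]:
    """Fit the DWI mono-exponential; returns (ADC in μm²/ms, S0).

    NaN marks an invalid pixel (non-positive samples, < 2 usable points, or
    a fitted ADC outside [0, 10] μm²/ms).
    """
    if series.axis_kind != "bvalue":
        raise ValueError("fit_adc expects a b-value series")
    v, b = series.values, series.axis
    if not np.all(v > 0) or np.unique(b).size < 2:
        return (math.nan, math.nan)
    slope, intercept = _weighted_loglinear(v, b)
    adc = mm2s_to_um2ms(-slope)  # slope is -ADC in mm²/s
    s0 = math.exp(intercept)
    if not (ADC_RANGE[0] <= adc <= ADC_RANGE[1]):
        return (math.nan, math.nan)
    return (adc, s0)


def fit_t2(series: SignalSeries) -> tuple[float, float]:
    """Fit the multi-echo T2 decay; returns (T2 in ms, S0).

    NaN marks an invalid pixel; fitted T2 must fall in (0, 2000] ms, so a
    non-decaying (constant or rising) series is invalid.
    """
    if series.axis_kind != "echo_time":
        raise ValueError("fit_t2 expects an echo-time series")
    v, te = series.values, series.axis
    if not np.all(v > 0) or np.unique(te).size < 2:
        return (math.nan, math.nan)
    slope, intercept = _weighted_loglinear(v, te)
    if slope >= 0.0:  # no decay -> T2 unbounded
        return (math.nan, math.nan)
    t2 = -1.0 / slope
    s0 = math.exp(intercept)
    if not (T2_RANGE[0] < t2 <= T2_RANGE[1]):
        return (math.nan, math.nan)
    return (t2, s0)


def compute_pse(
    series: SignalSeries, baseline_frames: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Percent signal enhancement of a DCE time course.

    PSE(t) = 100 * (S(t) - S_base) / S_base with S_base the mean of the
    first ``baseline_frames`` samples. Returns (pse, t) with the time axis
    re-zeroed at the last baseline frame; frames before it carry t < 0.
    A non-positive baseline yields an all-NaN curve (invalid pixel).
    """
    if series.axis_kind != "time":
        raise ValueError("compute_pse expects a time series")
    n = series.values.size
    if not (1 <= baseline_frames < n):
        raise ValueError("baseline_frames must be in [1, len(series))")
    s_base = float(series.values[:baseline_frames].mean())
    t = series.axis - series.axis[baseline_frames - 1]
    if s_base <= 0:
        return np.full(n, np.nan), t
    pse = 100.0 * (series.values - s_base) / s_base
    return pse, t


def emm_curve(t: np.ndarray, A: float, alpha: float, beta: float) -> np.ndarray:
    """PSE(t) = A (1 - e^{-alpha t}) e^{-beta t} for t >= 0."""
    return A * (1.0 - np.exp(-alpha * t)) * np.exp(-beta * t)


def _emm_residual(params: np.ndarray, t: np.ndarray, pse: np.ndarray) -> np.ndarray:
    return emm_curve(t, *params) - pse


def fit_emm(pse: np.ndarray, t: np.ndarray) -> EMMFit:
    """Fit the empirical enhancement model to a PSE curve.

    Only post-baseline samples (t >= 0) are fitted; at least 6 are required.
    Bounded least squares from a data-driven start (A0 = max PSE, alpha0 from
    the time to half-max, beta0 = 1e-3); if that start fails to converge, a
    fixed 3x3x3 initializer grid is tried and the best-RMSE fit returned.
    """
    pse = np.asarray(pse, dtype=float)
    t = np.asarray(t, dtype=float)
    keep = t >= 0
    pse, t = pse[keep], t[keep]
    if pse.size < 6:
        raise ValueError("need at least 6 post-baseline points")
    if not np.all(np.isfinite(pse)):
        return EMMFit(math.nan, math.nan, math.nan, math.nan, converged=False)

    pmax = float(pse.max())
    a0 = min(max(pmax, 1e-6), EMM_BOUNDS[1][0])
    above = np.nonzero(pse >= 0.5 * pmax)[0]
    if pmax > 0 and above.size and t[above[0]] > 0:
        alpha0 = min(math.log(2.0) / t[above[0]], EMM_BOUNDS[1][1])
    else:
        alpha0 = 0.1
    starts = [(a0, alpha0, 1e-3)]

    def _solve(x0):
        return least_squares(
            _emm_residual, x0=np.asarray(x0), bounds=EMM_BOUNDS, args=(t, pse)
        )

    best = None
    res = _solve(starts[0])
    if res.success:
        best = res
    else:
        # multi-start fallback on a fixed grid, best RMSE wins
        for fa in (0.5, 1.0, 1.5):
            for al in (0.01, 0.1, 1.0):
                for be in (1e-4, 1e-3, 1e-2):
                    r = _solve((max(fa * a0, 1e-6), al, be))
                    if r.success and (best is None or r.cost < best.cost):
                        best = r
    if best is None:
        return EMMFit(math.nan, math.nan, math.nan, math.nan, converged=False)
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    A, alpha, beta = (float(x) for x in best.x)
    return EMMFit(A, alpha, beta, rmse)


def _fit_loglinear_map(
    stack: np.ndarray, axis: np.ndarray, model: str
) -> ParameterMap:
    """Vectorized weighted log-linear fit over a (H, W, N) stack."""
    h, w, n = stack.shape
    usable = np.all(np.isfinite(stack), axis=-1) & np.all(stack > 0, axis=-1)
    safe = np.where(stack > 0, stack, 1.0)
    wts = safe**2
    y = np.log(safe)
    x = axis.reshape(1, 1, n)
    sw = wts.sum(-1)
    sx = (wts * x).sum(-1)
    sxx = (wts * x * x).sum(-1)
    sy = (wts * y).sum(-1)
    sxy = (wts * x * y).sum(-1)
    denom = sw * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom != 0, (sw * sxy - sx * sy) / denom, 0.0)
        intercept = np.where(denom != 0, (sy - slope * sx) / sw, sy / sw)
    s0 = np.exp(intercept)
    if model == "adc":
        grid = mm2s_to_um2ms(-slope)
        valid = usable & (grid >= ADC_RANGE[0]) & (grid <= ADC_RANGE[1])
        name = "ADC"
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            grid = np.where(slope < 0, -1.0 / slope, np.nan)
        valid = usable & np.isfinite(grid) & (grid > T2_RANGE[0]) & (grid <= T2_RANGE[1])
        name = "T2"
    # predicted signal S0 * exp(slope * x); residual RMS in signal units
    pred = s0[..., None] * np.exp(slope[..., None] * x)
    rms = np.sqrt(np.mean((pred - stack) ** 2, axis=-1))
    grid = np.where(valid, grid, np.nan)
    return ParameterMap(name, grid, UNITS[name], valid, np.where(usable, rms, np.nan))


def fit_map(
    stack: np.ndarray,
    axis: np.ndarray,
    model: Literal["adc", "t2", "emm"],
    baseline_frames: int = 3,
    mask: np.ndarray | None = None,
) -> ParameterMap | dict[str, ParameterMap]:
    """Apply a pixel fit across a (rows, cols, samples) signal stack.

    For ``adc``/``t2`` returns a single :class:`ParameterMap`. For ``emm``
    returns a dict of maps ``{"ALPHA", "A", "BETA"}``; because the nonlinear
    fit runs per pixel, an optional boolean ``mask`` restricts it to a region
    (pixels outside are invalid).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[-1] == 0 or stack.shape[0] == 0:
        raise ValueError("stack must be (rows, cols, samples) and non-empty")
    axis = np.asarray(axis, dtype=float)
    if axis.size != stack.shape[-1]:
        raise ValueError("axis length does not match stack")

    if model in ("adc", "t2"):
        return _fit_loglinear_map(stack, axis, model)
    if model != "emm":
        raise ValueError(f"unknown model {model!r}")

    h, w, _ = stack.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    grids = {k: np.full((h, w), np.nan) for k in ("ALPHA", "A", "BETA")}
    valid = np.zeros((h, w), dtype=bool)
    rms = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            series = SignalSeries(stack[r, c], axis, "time")
            pse, tt = compute_pse(series, baseline_frames)
            if not np.all(np.isfinite(pse)):
                continue
            fit = fit_emm(pse, tt)
            if not fit.converged:
                continue
            grids["A"][r, c] = fit.A
            grids["ALPHA"][r, c] = fit.alpha
            grids["BETA"][r, c] = fit.beta
            rms[r, c] = fit.rmse
            valid[r, c] = True
    return {
        name: ParameterMap(name, grids[name], UNITS[name], valid.copy(), rms.copy())
        for name in ("ALPHA", "A", "BETA")
    }
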