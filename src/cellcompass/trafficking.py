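"""Trafficking maps and protrusion–secretion cross-correlation.

A trafficking map mirrors the morphodynamic map geometrically: for each
frame, the mean fluorescence intensity is sampled along the straight ray
from the Golgi centroid to each of the contour markers (samples inside
the Golgi mask are excluded, suppressing the organelle's own signal).
Cross-correlating a trafficking map against the companion morphodynamic
map row by row yields the time lag by which secretion follows
protrusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .morphomap import MorphodynamicMap

__all__ = [
    "TraffickingMap",
    "XcorrResult",
    "build_trafficking_map",
    "normalize_stack",
    "crosscorrelate_maps",
    "extract_peak_lag",
]


@dataclass
class TraffickingMap:
    """``(n_markers, T)`` mean ray intensities, rows aligned with the
    companion morphodynamic map's markers."""

    values: np.ndarray
    dt: float = 1.0
    golgi_centroids: np.ndarray | None = None


@dataclass
class XcorrResult:
    """Cross-correlation curve(s) between two maps.

    ``lags`` spans ``[-max_lag, +max_lag]`` frames (scaled by ``dt``); a
    POSITIVE peak lag means the first map (protrusion) precedes the
    second (trafficking).  ``curve`` is the row-averaged normalized
    cross-covariance; ``per_row`` keeps the individual rows.
    """

    lags: np.ndarray
    curve: np.ndarray
    per_row: np.ndarray
    dt: float = 1.0

    @property
    def peak_lag(self) -> float:
        return float(self.lags[np.nanargmax(self.curve)])


def build_trafficking_map(
    stack,
    golgi_centroids,
    contour_markers,
    golgi_masks=None,
    dt: float = 1.0,
) -> TraffickingMap:
    """Mean intensity along Golgi-to-marker rays, per frame and marker.

    For frame ``t`` and marker ``i`` the segment from the Golgi centroid
    to the marker is sampled at ``ceil(ray length)`` evenly spaced points
    by bilinear interpolation; samples falling inside the Golgi mask are
    discarded and the value is the mean of the rest.  A ray entirely
    inside the mask gives NaN.

    Parameters
    ----------
    stack : (T, H, W) image stack
    golgi_centroids : (T, 2) or (2,) Golgi centre(s), (x, y)
    contour_markers : sequence of (n, 2) marker arrays, or one shared set
    golgi_masks : optional (T, H, W) or (H, W) boolean mask(s)
    """
    stack = np.asarray(stack, dtype=float)
    T = stack.shape[0]
    gc = np.asarray(golgi_centroids, dtype=float)
    if gc.ndim == 1:
        gc = np.tile(gc, (T, 1))
    markers_per_frame = (
        [np.asarray(contour_markers[t], float) for t in range(T)]
        if isinstance(contour_markers, (list, tuple))
        else [np.asarray(contour_markers, float)] * T
    )
    n = len(markers_per_frame[0])
    values = np.full((n, T), np.nan)
    for t in range(T):
        img = stack[t]
        mask = None
        if golgi_masks is not None:
            gm = np.asarray(golgi_masks)
            mask = gm[t] if gm.ndim == 3 else gm
        start = gc[t]
        for i, end in enumerate(markers_per_frame[t]):
            length = np.hypot(*(end - start))
            k = max(int(np.ceil(length)), 2)
            ts = np.linspace(0.0, 1.0, k)
            pts = start[None, :] + ts[:, None] * (end - start)[None, :]
            coords = np.vstack([pts[:, 1], pts[:, 0]])  # row, col
            vals = map_coordinates(img, coords, order=1, mode="nearest")
            if mask is not None:
                inside = map_coordinates(mask.astype(float), coords, order=0) > 0.5
                vals = vals[~inside]
            if len(vals):
                values[i, t] = vals.mean()
    return TraffickingMap(values=values, dt=dt, golgi_centroids=gc)


def normalize_stack(stack) -> np.ndarray:
    """Rescale every frame to the mean and SD of frame 0.

    A simple affine stand-in for bleach correction; the downstream lag
    estimate is invariant to per-frame affine intensity changes, so the
    exact correction scheme does not matter for the cross-correlation.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with T >= 2")
    mu0, sd0 = stack[0].mean(), stack[0].std()
    out = np.empty_like(stack)
    for t in range(stack.shape[0]):
        mu, sd = stack[t].mean(), stack[t].std()
        scale = sd0 / sd if sd > 0 else 1.0
        out[t] = (stack[t] - mu) * scale + mu0
    return out


def _norm_xcov(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-covariance of two 1-D series for lags
    ``-max_lag..max_lag``; positive lag = ``a`` leads ``b``.

    Means and norms are taken over the overlapping segment of each lag
    (per-lag Pearson correlation): a truncated copy of a signal then
    correlates to exactly 1 at its true shift, without the edge bias a
    global-mean subtraction introduces.
    """
    out = np.full(2 * max_lag + 1, np.nan)
    T = len(a)
    for k, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            x, y = a[: T - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: T + lag]
        good = np.isfinite(x) & np.isfinite(y)
        if good.sum() < 3:
            continue
        xg = x[good] - x[good].mean()
        yg = y[good] - y[good].mean()
        denom = np.sqrt(np.sum(xg * xg) * np.sum(yg * yg))
        if denom > 0:
            out[k] = np.sum(xg * yg) / denom
    return out


def crosscorrelate_maps(
    morpho: MorphodynamicMap | np.ndarray,
    traffic: TraffickingMap | np.ndarray,
    max_lag: int | None = None,
    dt: float | None = None,
) -> XcorrResult:
    """Row-wise normalized cross-covariance between two maps.

    Each marker row of both maps is mean-subtracted and cross-correlated;
    rows containing only missing values are dropped from the average.  A
    positive lag of the resulting curve means the first map's signal
    (protrusion) precedes the second's (trafficking).
    """
    a = morpho.values if isinstance(morpho, MorphodynamicMap) else np.asarray(morpho, float)
    b = traffic.values if isinstance(traffic, TraffickingMap) else np.asarray(traffic, float)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    n, T = a.shape
    if max_lag is None:
        max_lag = max(T // 3, 1)
    if dt is None:
        dt = morpho.dt if isinstance(morpho, MorphodynamicMap) else 1.0
    per_row = np.full((n, 2 * max_lag + 1), np.nan)
    for i in range(n):
        if np.any(np.isfinite(a[i])) and np.any(np.isfinite(b[i])):
            per_row[i] = _norm_xcov(a[i], b[i], max_lag)
    good = ~np.all(np.isnan(per_row), axis=1)
    curve = np.nanmean(per_row[good], axis=0)
    lags = np.arange(-max_lag, max_lag + 1) * dt
    return XcorrResult(lags=lags, curve=curve, per_row=per_row, dt=dt)


def extract_peak_lag(result: XcorrResult):
    """Sub-frame peak lag from a quadratic fit around the maximum.

    Fits a parabola through the maximum sample and its two neighbours;
    a maximum sitting on the domain edge cannot be refined and is
    returned as-is with ``edge=True``.

    Returns
    -------
    (lag, edge_flag) : peak lag in the curve's time unit, and whether the
    maximum sat on the edge of the lag range.
    """
    y = result.curve
    k = int(np.nanargmax(y))
    if k == 0 or k == len(y) - 1:
        return float(result.lags[k]), True
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    step = result.lags[1] - result.lags[0]
    return float(result.lags[k] + frac * step), False
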