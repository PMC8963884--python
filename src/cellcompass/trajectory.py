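"""Trajectory-level migration statistics.

Implements the persistence toolbox used on single-cell tracks: step
directions, direction autocorrelation with exponential persistence-time
fitting, directionality ratio, the angle between an internal polarity
axis (nucleus -> Golgi) and the direction of movement, reorientation
curves against a target point, cumulative reorientation fractions, and
the alignment index (mean resultant length of paired angle differences).

Angles follow the mathematical convention: radians internally,
counterclockwise positive, measured from the +x axis.  Zero-displacement
steps yield missing (NaN) directions rather than a spurious 0°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import circmean, circstd

__all__ = [
    "AutocorrResult",
    "step_directions",
    "direction_autocorrelation",
    "fit_persistence_time",
    "directionality_ratio",
    "axis_movement_angles",
    "reorientation_series",
    "cumulative_reorientation",
    "alignment_index",
]


@dataclass
class AutocorrResult:
    """Direction autocorrelation curve and its exponential fit.

    ``lags`` are in time units (``dt`` times the step lag), ``ac`` is the
    dimensionless autocorrelation with ``ac[0] == 1``.  ``tau`` is the
    fitted persistence time (same unit as ``lags``), NaN when the fit
    failed; ``tau_censored`` marks tracks straighter than the fit range
    can resolve (AC never decays below 1/e), whose ``tau`` is reported at
    the censoring bound.
    """

    lags: np.ndarray
    ac: np.ndarray
    tau: float = np.nan
    tau_censored: bool = False
    fit_max_lag: float = np.nan
    fit_residual: float = np.nan


def _as_xy(track) -> np.ndarray:
    xy = np.asarray(track, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("track must be an (N, 2) array of positions")
    return xy


def step_directions(track) -> np.ndarray:
    """Headings (radians) of consecutive displacements; NaN for zero steps."""
    xy = _as_xy(track)
    if len(xy) < 2:
        raise ValueError("need at least 2 points")
    d = np.diff(xy, axis=0)
    theta = np.arctan2(d[:, 1], d[:, 0])
    theta[np.all(d == 0, axis=1)] = np.nan
    return theta


def direction_autocorrelation(track, dt: float = 1.0, max_lag: int | None = None) -> AutocorrResult:
    """Mean cosine of the heading change as a function of the time lag.

    ``AC(lag) = < cos(theta(t + lag) - theta(t)) >_t`` with missing
    headings skipped pairwise; ``AC(0) = 1`` by construction.
    """
    theta = step_directions(track) if np.asarray(track).ndim == 2 else np.asarray(track, float)
    m = len(theta)
    if np.sum(np.isfinite(theta)) < 3:
        raise ValueError("need at least 3 valid step directions")
    if max_lag is None:
        max_lag = m - 1
    max_lag = min(max_lag, m - 1)
    ac = np.full(max_lag + 1, np.nan)
    ac[0] = 1.0
    for lag in range(1, max_lag + 1):
        d = theta[lag:] - theta[:-lag]
        good = np.isfinite(d)
        if good.any():
            ac[lag] = np.mean(np.cos(d[good]))
    return AutocorrResult(lags=np.arange(max_lag + 1) * dt, ac=ac)


def fit_persistence_time(
    result: AutocorrResult,
    fit_frac: float = 1.0 / 3.0,
    track_duration: float | None = None,
    tau_bound: float | None = None,
    decay_factor: float | None = 3.0,
) -> AutocorrResult:
    """Fit ``exp(-lag / tau)`` to an autocorrelation curve.

    The fit runs over lags from one time step up to ``fit_frac`` of the
    track duration, further capped at ``decay_factor`` times the lag of
    the first 1/e crossing when the curve decays inside the range: for
    tracks much longer than the persistence time the tail of the curve
    carries no signal, only sampling noise, and including it inflates
    the fit variance severalfold.  Set ``decay_factor=None`` to fit the
    full ``fit_frac`` range.

    ``tau`` is bounded above by ``tau_bound`` (default: the track
    duration); a fit pinned at the bound, or a curve that never drops
    below 1/e inside the range, is flagged censored with ``tau``
    reported at the bound.  Non-convergence yields ``tau = NaN``.

    Returns a new :class:`AutocorrResult` with the fit fields filled in.
    """
    lags, ac = result.lags, result.ac
    if len(lags) < 5:
        raise ValueError("need AC over at least 5 lags")
    duration = track_duration if track_duration is not None else lags[-1] + lags[1]
    lag_max = fit_frac * duration
    bound = tau_bound if tau_bound is not None else duration
    if decay_factor is not None:
        crossing = np.flatnonzero((ac < np.exp(-1.0)) & (lags <= lag_max))
        if len(crossing):
            lag_max = min(lag_max, max(decay_factor * lags[crossing[0]], 5 * lags[1]))
    sel = (lags > 0) & (lags <= lag_max) & np.isfinite(ac)
    x, y = lags[sel], ac[sel]
    if len(x) < 3:
        raise ValueError("fewer than 3 valid lags inside the fit range")

    censored = not np.any(y < np.exp(-1.0))
    below = np.flatnonzero(y < np.exp(-1.0))
    p0 = x[below[0]] if len(below) else bound / 2.0
    try:
        popt, _ = optimize.curve_fit(
            lambda l, tau: np.exp(-l / tau),
            x,
            y,
            p0=[min(max(p0, x[0]), bound)],
            bounds=(1e-9, bound),
            maxfev=2000,
        )
        tau = float(popt[0])
        resid = float(np.sqrt(np.mean((np.exp(-x / tau) - y) ** 2)))
    except RuntimeError:
        return AutocorrResult(lags, ac, np.nan, False, lag_max, np.nan)
    if tau >= 0.99 * bound:
        tau, censored = bound, True
    return AutocorrResult(lags, ac, tau, censored, lag_max, resid)


def directionality_ratio(track) -> float:
    """Net displacement over total path length, in (0, 1]."""
    xy = _as_xy(track)
    if len(xy) < 2:
        raise ValueError("need at least 2 points")
    path = np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))
    if path == 0:
        raise ValueError("zero path length")
    return float(np.linalg.norm(xy[-1] - xy[0]) / path)


def _signed_angle(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Signed angle (radians, CCW positive) rotating ``v_from`` onto ``v_to``."""
    cross = v_from[..., 0] * v_to[..., 1] - v_from[..., 1] * v_to[..., 0]
    dot = np.einsum("...i,...i->...", v_from, v_to)
    return np.arctan2(cross, dot)


def axis_movement_angles(track, nucleus, golgi, degrees: bool = True):
    """Per-frame angle between the nucleus->Golgi axis and the movement.

    The angle is signed, counterclockwise positive (+90° = Golgi
    perpendicular-left of the motion), in ``(-180°, 180°]``.  Frames with
    zero displacement or a missing organelle give NaN.  The summary is
    the circular mean and circular standard deviation over frames.

    Returns
    -------
    angles : per-step array (degrees by default)
    circ_mean, circ_sd : floats (same unit)
    """
    xy = _as_xy(track)
    nuc = _as_xy(nucleus)
    gol = _as_xy(golgi)
    if not (len(xy) == len(nuc) == len(gol)):
        raise ValueError("track, nucleus, golgi must share frame count")
    move = np.diff(xy, axis=0)
    axis = (gol - nuc)[:-1]
    ang = _signed_angle(move, axis)
    bad = (np.linalg.norm(move, axis=1) == 0) | (np.linalg.norm(axis, axis=1) == 0)
    bad |= ~np.all(np.isfinite(axis), axis=1) | ~np.all(np.isfinite(move), axis=1)
    ang[bad] = np.nan
    ok = np.isfinite(ang)
    if ok.any():
        mu = float(circmean(ang[ok], high=np.pi, low=-np.pi))
        sd = float(circstd(ang[ok], high=np.pi, low=-np.pi))
    else:
        mu = sd = np.nan
    if degrees:
        return np.degrees(ang), np.degrees(mu), np.degrees(sd)
    return ang, mu, sd


def reorientation_series(nucleus, golgi, target) -> np.ndarray:
    """Unwrapped angle (degrees) between the N->G axis and the N->target axis.

    The per-frame angle is wrapped to ``[0, 2pi)`` and then unwrapped to a
    continuous curve (no 2pi jumps); 0° means the polarity axis points at
    the target.
    """
    nuc, gol, tgt = _as_xy(nucleus), _as_xy(golgi), _as_xy(target)
    if not (len(nuc) == len(gol) == len(tgt)):
        raise ValueError("point series must share frame count")
    ang = _signed_angle(tgt - nuc, gol - nuc)
    wrapped = np.mod(ang, 2 * np.pi)
    return np.degrees(np.unwrap(wrapped))


def cumulative_reorientation(angle_curves, times, threshold_deg: float = 30.0):
    """Fraction of cells reoriented as a function of time.

    For every cell the reorientation time is the first time its
    unwrapped ``|angle|`` curve drops to ``threshold_deg`` or below.
    The cumulative count is normalised by the total number of cells, so
    cells that never cross stay out of the numerator but keep the curve
    below 1.

    Parameters
    ----------
    angle_curves
        Iterable of per-cell angle arrays (degrees) on the common
        ``times`` grid.
    times
        Shared time axis.

    Returns
    -------
    fraction : array aligned with ``times``
    crossing_times : per-cell first-crossing time (NaN when never)
    """
    times = np.asarray(times, dtype=float)
    crossing = []
    for curve in angle_curves:
        curve = np.asarray(curve, dtype=float)
        if curve.shape != times.shape:
            raise ValueError("each curve must match the time grid")
        hits = np.flatnonzero(np.abs(curve) <= threshold_deg)
        crossing.append(times[hits[0]] if len(hits) else np.nan)
    crossing = np.array(crossing)
    n = len(crossing)
    if n == 0:
        raise ValueError("no cells")
    frac = np.array([np.sum(crossing[np.isfinite(crossing)] <= t) for t in times]) / n
    return frac, crossing


def alignment_index(axis_angles, motion_angles=None) -> float:
    """Angular dispersion r of paired angle differences, in [0, 1].

    ``r = sqrt(<sin theta>^2 + <cos theta>^2)`` with
    ``theta_i = axis_i - motion_i`` (or the given angles directly when
    ``motion_angles`` is None).  1 means perfect alignment, 0 uniform
    dispersion.  NaN pairs are skipped.
    """
    theta = np.asarray(axis_angles, dtype=float)
    if motion_angles is not None:
        theta = theta - np.asarray(motion_angles, dtype=float)
    theta = theta[np.isfinite(theta)]
    if len(theta) == 0:
        raise ValueError("no valid angle pairs")
    return float(np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta))))
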