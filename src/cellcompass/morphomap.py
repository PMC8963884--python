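"""Morphodynamic maps of cell-edge motion.

A morphodynamic map is a ``n_markers x (T-1)`` array of signed edge speeds
built from a sequence of closed cell contours: each contour is resampled to
``n_markers`` equidistant points ("markers"), markers are paired between
consecutive frames by the circular shift that minimises the total squared
displacement, and the speed of each marker is signed positive where the
edge moves outward (protrusion) and negative where it moves inward
(retraction).  Columns can be recentred so that a chosen reference axis
(e.g. the nucleus-to-Golgi direction) always sits on the middle row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from shapely.geometry import Polygon

__all__ = [
    "MorphodynamicMap",
    "ensure_ccw",
    "resample_contour",
    "contour_centroid",
    "outward_normals",
    "match_contours",
    "build_morphomap",
    "recenter_map",
    "undo_recenter",
    "mean_protrusion_profile",
]

DEFAULT_N_MARKERS = 100


@dataclass
class MorphodynamicMap:
    """Signed edge-speed map.

    Attributes
    ----------
    values
        ``(n_markers, T-1)`` array, positive = protrusion, units are
        px/frame by default, or µm/min when ``pixel_scale`` and ``dt``
        were supplied to :func:`build_morphomap`.
    dt
        Time per frame in the time unit of ``values`` (1.0 = per frame).
    marker_angles
        Optional ``(n_markers, T-1)`` array of the direction (radians) of
        each marker from the cell centroid, used by :func:`recenter_map`.
        When absent markers are assumed uniformly distributed in angle.
    centroids
        Optional ``(T-1, 2)`` cell-centroid positions per column.
    row_offsets
        Per-column circular shifts applied by :func:`recenter_map`
        (``None`` for a raw map).  Recentring is a pure row permutation
        per column and is exactly invertible.
    reference_angles
        The per-column reference angles (radians) a recentred map was
        aligned to.
    unshifted_columns
        Boolean flags marking columns left untouched because the
        reference was missing there.
    """

    values: np.ndarray
    dt: float = 1.0
    marker_angles: np.ndarray | None = None
    centroids: np.ndarray | None = None
    row_offsets: np.ndarray | None = None
    reference_angles: np.ndarray | None = None
    unshifted_columns: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _polygon_or_array(contour) -> np.ndarray:
    if isinstance(contour, Polygon):
        xy = np.asarray(contour.exterior.coords)[:-1]
    else:
        xy = np.asarray(contour, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("contour must be an (N, 2) array or shapely Polygon")
        if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
    if len(xy) < 3:
        raise ValueError("contour needs at least 3 distinct vertices")
    return xy


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(contour) -> np.ndarray:
    """Return the contour vertices in counterclockwise order.

    A consistent orientation is required for circular-shift marker
    matching and for the outward-normal sign convention.
    """
    xy = _polygon_or_array(contour)
    if _signed_area(xy) < 0:
        xy = xy[::-1]
    return xy


def contour_centroid(contour) -> np.ndarray:
    """Area centroid of a closed contour (shoelace formula)."""
    xy = _polygon_or_array(contour)
    c = Polygon(xy).centroid
    return np.array([c.x, c.y])


def resample_contour(contour, n_markers: int = DEFAULT_N_MARKERS) -> np.ndarray:
    """Resample a simple closed polygon to equidistant arclength markers.

    Markers are returned counterclockwise.  The start marker is placed at
    the vertex with the smallest angle (in ``[0, 2pi)``) from the +x axis
    about the centroid, which makes the operation deterministic; any
    residual frame-to-frame dependence is absorbed by marker matching.

    Parameters
    ----------
    contour
        ``(N, 2)`` vertex array or shapely ``Polygon``; first/last vertex
        may repeat.
    n_markers
        Number of output markers (100 by default).

    Returns
    -------
    ``(n_markers, 2)`` array of marker positions with consecutive
    arclength gaps equal to ``perimeter / n_markers``.
    """
    xy = ensure_ccw(contour)
    centroid = contour_centroid(xy)
    # epsilon keeps a vertex at angle 0 - eps from wrapping to ~2*pi
    ang = np.mod(
        np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0]) + 1e-9, 2 * np.pi
    )
    start = int(np.argmin(ang))
    xy = np.roll(xy, -start, axis=0)

    closed = np.vstack([xy, xy[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = arclen[-1]
    if perimeter <= 0:
        raise ValueError("degenerate contour: zero perimeter")
    target = np.arange(n_markers) * perimeter / n_markers
    mx = np.interp(target, arclen, closed[:, 0])
    my = np.interp(target, arclen, closed[:, 1])
    return np.column_stack([mx, my])


def outward_normals(markers: np.ndarray, smooth_window: int = 5) -> np.ndarray:
    """Unit outward normals of a counterclockwise marker loop.

    The local tangent is estimated by central differences on markers
    smoothed with a circular moving average (``smooth_window`` points) to
    resist vertex noise; the outward normal is the tangent rotated -90°.
    """
    sm = uniform_filter1d(markers, size=smooth_window, axis=0, mode="wrap")
    tang = (np.roll(sm, -1, axis=0) - np.roll(sm, 1, axis=0)) / 2.0
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang /= norm
    # CCW loop: interior lies to the left of the tangent, so rotating the
    # tangent clockwise points outward.
    return np.column_stack([tang[:, 1], -tang[:, 0]])


def match_contours(markers_t: np.ndarray, markers_t1: np.ndarray):
    """Pair markers between consecutive frames by exhaustive circular shift.

    Minimises ``sum_i |m_i(t) - m_{i+s}(t+dt)|^2`` over all ``n`` circular
    shifts ``s``.  Ties are broken by the smallest absolute signed shift,
    then by the smaller signed shift.

    Returns
    -------
    s_star : int
        The optimal shift, in ``[0, n)``.
    displacements : ``(n, 2)`` array
        ``m_{i+s*}(t+dt) - m_i(t)`` for each marker ``i``.
    """
    m0 = np.asarray(markers_t, dtype=float)
    m1 = np.asarray(markers_t1, dtype=float)
    if m0.shape != m1.shape:
        raise ValueError("marker sets must have equal size")
    n = len(m0)
    idx = (np.arange(n)[None, :] + np.arange(n)[:, None]) % n  # idx[s, i] = i + s
    diffs = m1[idx] - m0[None, :, :]
    ssd = np.einsum("sij,sij->s", diffs, diffs)
    best = np.flatnonzero(np.isclose(ssd, ssd.min(), rtol=1e-12, atol=1e-9))
    signed = (best + n // 2) % n - n // 2
    order = np.lexsort((signed, np.abs(signed)))
    s_star = int(best[order[0]])
    return s_star, diffs[s_star]


def _marker_angles(markers: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    d = markers - centroid
    return np.arctan2(d[:, 1], d[:, 0])


def build_morphomap(
    contours,
    dt: float = 1.0,
    pixel_scale: float = 1.0,
    n_markers: int = DEFAULT_N_MARKERS,
) -> MorphodynamicMap:
    """Build the morphodynamic map of a contour sequence.

    Each contour is resampled to ``n_markers`` equidistant markers and
    paired with the next frame via :func:`match_contours`.  The entry
    ``values[i, t]`` is the displacement magnitude of marker ``i`` between
    frames ``t`` and ``t+1`` divided by ``dt``, signed by the projection
    of the displacement on the outward normal (positive = protrusion).
    Rows are aligned across columns by composing the per-frame matching
    shifts, so a row follows the same material point over time.

    A frame whose contour fails to resample yields a column of NaNs and a
    warning rather than an exception.
    """
    T = len(contours)
    if T < 2:
        raise ValueError("need at least two frames")
    markers, cents = [], []
    for k, c in enumerate(contours):
        try:
            m = resample_contour(c, n_markers)
        except (ValueError, Exception) as exc:  # degenerate frame
            if not isinstance(exc, ValueError):
                raise
            warnings.warn(f"frame {k}: contour failed to resample ({exc})")
            m = None
        markers.append(m)
        cents.append(contour_centroid(c) if m is not None else np.full(2, np.nan))

    values = np.full((n_markers, T - 1), np.nan)
    angles = np.full((n_markers, T - 1), np.nan)
    centroids = np.full((T - 1, 2), np.nan)
    offset = 0
    for t in range(T - 1):
        m0, m1 = markers[t], markers[t + 1]
        if m0 is None or m1 is None:
            continue
        s, disp = match_contours(m0, m1)
        normals = outward_normals(m0)
        proj = np.einsum("ij,ij->i", disp, normals)
        speed = np.linalg.norm(disp, axis=1) * np.sign(proj) * pixel_scale / dt
        # roll so row r is the frame-0 identity of the marker
        values[:, t] = np.roll(speed, -offset)
        angles[:, t] = np.roll(_marker_angles(m0, cents[t]), -offset)
        centroids[t] = cents[t]
        offset = (offset + s) % n_markers
    return MorphodynamicMap(
        values=values, dt=dt, marker_angles=angles, centroids=centroids
    )


def recenter_map(
    mmap: MorphodynamicMap,
    reference_angles: np.ndarray,
) -> MorphodynamicMap:
    """Circularly shift each column so the reference axis sits mid-map.

    For every column the marker whose direction from the cell centroid is
    nearest (circularly) to the reference angle is moved to row
    ``n_markers // 2``.  The shifts are stored in ``row_offsets``; columns
    with a missing (NaN) reference are left unshifted and flagged.  The
    operation permutes values within each column and is exactly inverted
    by :func:`undo_recenter`.
    """
    ref = np.asarray(reference_angles, dtype=float)
    n, T = mmap.values.shape
    if ref.shape != (T,):
        raise ValueError(f"need one reference angle per column ({T}), got {ref.shape}")
    if mmap.marker_angles is not None:
        ang = mmap.marker_angles
    else:
        ang = np.tile(2 * np.pi * np.arange(n)[:, None] / n, (1, T))
    out = np.empty_like(mmap.values)
    out_ang = np.empty_like(ang)
    offsets = np.zeros(T, dtype=int)
    unshifted = np.zeros(T, dtype=bool)
    mid = n // 2
    for t in range(T):
        if not np.isfinite(ref[t]) or not np.any(np.isfinite(ang[:, t])):
            out[:, t] = mmap.values[:, t]
            out_ang[:, t] = ang[:, t]
            unshifted[t] = True
            continue
        d = np.angle(np.exp(1j * (ang[:, t] - ref[t])))
        r_star = int(np.nanargmin(np.abs(d)))
        offsets[t] = mid - r_star
        out[:, t] = np.roll(mmap.values[:, t], offsets[t])
        out_ang[:, t] = np.roll(ang[:, t], offsets[t])
    return MorphodynamicMap(
        values=out,
        dt=mmap.dt,
        marker_angles=out_ang,
        centroids=mmap.centroids,
        row_offsets=offsets,
        reference_angles=ref,
        unshifted_columns=unshifted,
    )


def undo_recenter(mmap: MorphodynamicMap) -> MorphodynamicMap:
    """Invert :func:`recenter_map` exactly using the stored offsets."""
    if mmap.row_offsets is None:
        raise ValueError("map carries no recentering offsets")
    out = np.empty_like(mmap.values)
    ang = None if mmap.marker_angles is None else np.empty_like(mmap.marker_angles)
    for t in range(mmap.n_columns):
        out[:, t] = np.roll(mmap.values[:, t], -mmap.row_offsets[t])
        if ang is not None:
            ang[:, t] = np.roll(mmap.marker_angles[:, t], -mmap.row_offsets[t])
    return MorphodynamicMap(
        values=out, dt=mmap.dt, marker_angles=ang, centroids=mmap.centroids
    )


def mean_protrusion_profile(maps):
    """Average edge-speed profile across a collection of recentred maps.

    Each map contributes its per-row time average; the profile is the mean
    of those row averages over cells, with the across-cell standard
    deviation as dispersion.  All maps must share ``n_markers`` and have
    been recentred to the same reference so that the middle row has the
    same meaning in every cell.

    Returns
    -------
    (mean, sd) : two ``(n_markers,)`` arrays
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty map collection")
    n = maps[0].values.shape[0]
    per_cell = []
    for m in maps:
        if m.values.shape[0] != n:
            raise ValueError("maps disagree on n_markers")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_cell.append(np.nanmean(m.values, axis=1))
    stack = np.vstack(per_cell)
    return np.nanmean(stack, axis=0), np.nanstd(stack, axis=0)
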