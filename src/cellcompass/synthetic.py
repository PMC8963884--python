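"""Synthetic inputs with known ground truth.

Every downstream stage of the package can be exercised without
microscopy data: persistent-random-walk tracks with a known persistence
time, contour movies realising a prescribed morphodynamic map, image
stacks whose ray-intensity pattern lags a protrusion map by a known
delay, and noisy blob images for the segmentation pipeline.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import disk as draw_disk

from .morphomap import MorphodynamicMap, outward_normals, resample_contour

__all__ = [
    "PRWParams",
    "SyntheticScene",
    "gen_prw_trajectory",
    "circle_contour",
    "gen_contour_movie",
    "gen_trafficking_stack",
    "gen_blob_image",
]


@dataclass
class PRWParams:
    """Persistent-random-walk parameters.

    ``speed`` is the (constant) step speed, ``tau`` the heading
    persistence time, ``dt`` the frame interval (same time unit as
    ``tau``; minutes throughout the package).  ``tau = inf`` is allowed
    and gives a perfectly straight track.
    """

    speed: float = 1.0
    tau: float = 120.0
    dt: float = 5.0
    n_frames: int = 200
    seed: int | None = None

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class SyntheticScene:
    """Bundle of mutually consistent synthetic inputs for one 'cell'."""

    contour_sequence: list | None = None
    truth_map: MorphodynamicMap | None = None
    nucleus_track: np.ndarray | None = None
    golgi_track: np.ndarray | None = None
    intensity_stack: np.ndarray | None = None
    golgi_mask: np.ndarray | None = None
    truth_rays: np.ndarray | None = None
    truth_lag: float | None = None


def gen_prw_trajectory(params: PRWParams) -> np.ndarray:
    """Simulate a 2-D persistent random walk.

    The heading performs a discrete angular random walk,
    ``theta(t + dt) = theta(t) + Normal(0, sqrt(2 dt / tau))``, whose
    direction autocorrelation is exactly ``exp(-lag / tau)``; position
    advances by ``speed * dt`` along the current heading each frame.

    Returns an ``(n_frames, 2)`` position array starting at the origin.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    sigma = 0.0 if np.isinf(params.tau) else np.sqrt(2.0 * params.dt / params.tau)
    theta0 = rng.uniform(0, 2 * np.pi)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(rng.normal(0, sigma, n - 2))])
    steps = params.speed * params.dt * np.column_stack([np.cos(theta), np.sin(theta)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return xy


def circle_contour(radius: float = 50.0, center=(0.0, 0.0), n_vertices: int = 200) -> np.ndarray:
    """Counterclockwise circular polygon, handy as an initial contour."""
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    return np.column_stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)])


def gen_contour_movie(
    truth_map,
    initial_contour,
    dt: float = 1.0,
) -> list[np.ndarray]:
    """Evolve a contour under a prescribed morphodynamic map.

    Inverts morphodynamic-map quantification: frame ``t+1`` is obtained
    by displacing each marker of frame ``t`` along its outward normal by
    ``values[i, t] * dt`` (explicit Euler; per-frame steps are assumed
    small relative to the cell radius).  If the evolved polygon becomes
    self-intersecting the movie is truncated at the last valid frame
    with a warning.

    Returns a list of ``(n_markers, 2)`` marker arrays, one per frame
    (``T`` frames for a map with ``T-1`` columns).
    """
    values = truth_map.values if isinstance(truth_map, MorphodynamicMap) else np.asarray(truth_map, float)
    n, ncol = values.shape
    contour = resample_contour(initial_contour, n)
    frames = [contour]
    for t in range(ncol):
        normals = outward_normals(contour)
        nxt = contour + normals * (values[:, t] * dt)[:, None]
        if not Polygon(nxt).is_valid:
            warnings.warn(
                f"contour self-intersects at frame {t + 1}; truncating movie"
            )
            break
        contour = nxt
        frames.append(contour)
    return frames


def _paint_ray(img, start, end, amplitude):
    """Add ``amplitude`` along the segment start->end (nearest-pixel line)."""
    length = int(np.ceil(np.hypot(*(np.asarray(end) - start)))) + 1
    ts = np.linspace(0.0, 1.0, length)
    pts = np.asarray(start)[None, :] + ts[:, None] * (np.asarray(end) - start)[None, :]
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, img.shape[1] - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, img.shape[0] - 1)
    img[rows, cols] = np.maximum(img[rows, cols], amplitude)


def gen_trafficking_stack(
    protrusion_map,
    lag_frames: int,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    cell_radius: float = 55.0,
    golgi_radius: float = 6.0,
    seed: int | None = None,
) -> SyntheticScene:
    """Image stack whose ray intensities lag a protrusion map.

    The scene is a circular cell centred in the frame with the Golgi at
    its centre.  At frame ``t`` the ray from the Golgi to contour marker
    ``i`` carries intensity proportional to
    ``max(protrusion_map[i, t - lag_frames], 0)`` (secretion follows
    protrusion, never retraction), plus i.i.d. Gaussian noise.  The
    noiseless ray amplitudes are returned as ``truth_rays`` for direct
    map-level tests.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lag_frames = int(lag_frames)
    values = protrusion_map.values if isinstance(protrusion_map, MorphodynamicMap) else np.asarray(protrusion_map, float)
    n, T = values.shape
    rng = np.random.default_rng(seed)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ang = 2 * np.pi * np.arange(n) / n
    marker_xy = np.column_stack([cx + cell_radius * np.cos(ang), cy + cell_radius * np.sin(ang)])

    truth = np.zeros((n, T))
    src = np.maximum(values, 0.0)
    if lag_frames >= 0:
        truth[:, lag_frames:] = src[:, : T - lag_frames] if lag_frames else src
    else:
        truth[:, : T + lag_frames] = src[:, -lag_frames:]

    stack = np.zeros((T, *shape), dtype=float)
    center = np.array([cx, cy])
    for t in range(T):
        for i in range(n):
            if truth[i, t] > 0:
                _paint_ray(stack[t], center, marker_xy[i], truth[i, t])
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)

    golgi_mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((cy, cx), golgi_radius, shape=shape)
    golgi_mask[rr, cc] = True

    contours = [marker_xy.copy() for _ in range(T)]
    return SyntheticScene(
        contour_sequence=contours,
        truth_map=protrusion_map if isinstance(protrusion_map, MorphodynamicMap) else MorphodynamicMap(values),
        golgi_track=np.tile(center, (T, 1)),
        intensity_stack=stack,
        golgi_mask=golgi_mask,
        truth_rays=truth,
        truth_lag=float(lag_frames),
    )


def gen_blob_image(
    n_blobs: int = 1,
    radii=12.0,
    intensities=1.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    seed: int | None = None,
    centers=None,
):
    """Grayscale image of disk-shaped blobs plus Gaussian noise.

    Blob centres are drawn uniformly inside the frame with a margin of
    one radius unless ``centers`` is given explicitly.  Returns
    ``(image, centers)`` with centres as ``(x, y)`` rows.
    """
    rng = np.random.default_rng(seed)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n_blobs,))
    intensities = np.broadcast_to(np.asarray(intensities, dtype=float), (n_blobs,))
    if centers is None:
        # rejection-sample well-separated centres so blobs never merge
        placed: list[np.ndarray] = []
        for r in radii:
            for _ in range(1000):
                c = np.array(
                    [rng.uniform(r + 2, shape[1] - r - 2), rng.uniform(r + 2, shape[0] - r - 2)]
                )
                if all(
                    np.linalg.norm(c - p) > r + r2 + 4 for p, r2 in zip(placed, radii)
                ):
                    placed.append(c)
                    break
            else:
                raise ValueError("could not place non-overlapping blobs")
        centers = np.vstack(placed)
    else:
        centers = np.asarray(centers, dtype=float)
    img = np.zeros(shape, dtype=float)
    for (x, y), r, a in zip(centers, radii, intensities):
        rr, cc = draw_disk((y, x), r, shape=shape)
        img[rr, cc] += a
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    return img, centers
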