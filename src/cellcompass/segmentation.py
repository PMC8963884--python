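"""Threshold segmentation and centroid tracking of labelled structures.

A fixed pipeline mirrors the classic fluorescence workflow: global
threshold (Otsu by default, fixed value per channel optionally) ->
binarise -> clear structures touching the border -> remove small objects
-> morphological closing with a disk -> fill holes -> per-component
centroids.  Tracking concatenates per-frame centroids by
nearest-to-previous selection and corrects for recorded stage movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure, morphology, segmentation as skseg
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "CentroidTrack",
    "segment_object",
    "track_centroids",
    "correct_stage_jumps",
]


@dataclass
class SegmentationConfig:
    """Pipeline knobs.

    ``threshold``: "otsu" for the automatic gray threshold, or a fixed
    numeric value (the original workflow tuned a slightly different
    range per structure, so no per-channel default is claimed).
    """

    threshold: float | str = "otsu"
    min_object_area: int = 64
    closing_radius: int = 10
    clear_border: bool = True

    def __post_init__(self):
        if self.min_object_area < 0 or self.closing_radius < 0:
            raise ValueError("areas and radii must be non-negative")


@dataclass
class SegmentationResult:
    mask: np.ndarray
    centroid: np.ndarray | None       # (x, y) of the selected object, None if empty
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def found(self) -> bool:
        return self.centroid is not None


@dataclass
class CentroidTrack:
    """Per-frame selected centroids (x, y) with gap flags."""

    positions: np.ndarray
    gap_flags: np.ndarray
    pixel_scale: float = 1.0


def segment_object(
    image,
    config: SegmentationConfig | None = None,
    previous_centroid=None,
) -> SegmentationResult:
    """Segment bright structures in a 2-D grayscale image.

    Returns all component centroids plus one *selected* centroid: the
    component nearest ``previous_centroid`` when given (useful when
    several regions of interest survive filtering), the largest
    component otherwise.  An image with nothing above threshold is a
    normal "no object" result, not an error.

    Coordinates are 0-based pixel centres with x = column, y = row.
    """
    config = config or SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")

    if config.threshold == "otsu":
        if np.ptp(img) == 0:
            return SegmentationResult(np.zeros(img.shape, bool), None)
        thr = threshold_otsu(img)
    else:
        thr = float(config.threshold)
    mask = img > thr
    if config.clear_border:
        mask = skseg.clear_border(mask)
    if config.min_object_area > 0:
        mask = morphology.remove_small_objects(mask, max_size=config.min_object_area - 1)
    if config.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(config.closing_radius))
    mask = binary_fill_holes(mask)

    labels = measure.label(mask)
    props = measure.regionprops(labels)
    if not props:
        return SegmentationResult(mask, None)
    cents = np.array([[p.centroid[1], p.centroid[0]] for p in props])  # (x, y)
    if previous_centroid is not None:
        k = int(np.argmin(np.linalg.norm(cents - np.asarray(previous_centroid), axis=1)))
    else:
        k = int(np.argmax([p.area for p in props]))
    return SegmentationResult(mask, cents[k], cents)


def track_centroids(candidates, initial_point, pixel_scale: float = 1.0) -> CentroidTrack:
    """Concatenate per-frame centroid candidates into one trajectory.

    ``candidates`` is a sequence (one entry per frame) of ``(k, 2)``
    candidate arrays (possibly empty).  Each frame selects the candidate
    closest to the previous selection (frame 0: closest to
    ``initial_point``); a frame with no candidate carries the previous
    position forward and is flagged as a gap.
    """
    frames = [np.asarray(c, dtype=float).reshape(-1, 2) for c in candidates]
    if all(len(f) == 0 for f in frames):
        raise ValueError("no candidate centroid in any frame")
    if len(frames[0]) == 0:
        raise ValueError("frame 0 has no candidate centroid")
    prev = np.asarray(initial_point, dtype=float)
    pos = np.empty((len(frames), 2))
    gaps = np.zeros(len(frames), dtype=bool)
    for t, cands in enumerate(frames):
        if len(cands) == 0:
            pos[t] = prev
            gaps[t] = True
            continue
        prev = cands[np.argmin(np.linalg.norm(cands - prev, axis=1))]
        pos[t] = prev
    return CentroidTrack(positions=pos, gap_flags=gaps, pixel_scale=pixel_scale)


def correct_stage_jumps(track_xy, stage_xy, pixel_scale: float = 1.0) -> np.ndarray:
    """Remove stage-movement jumps from an image-coordinate track.

    ``corrected(t) = raw(t) + pixel_scale * (stage(t) - stage(0))``: a
    cell pinned at the image centre by a moving stage maps back to its
    true, continuous path in sample coordinates.
    """
    raw = np.asarray(track_xy, dtype=float)
    stage = np.asarray(stage_xy, dtype=float)
    if raw.shape != stage.shape:
        raise ValueError("track and stage position series must have equal shape")
    return raw + pixel_scale * (stage - stage[0])
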