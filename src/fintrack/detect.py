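"""Blob detection in grayscale video by background subtraction.

The pipeline mirrors classic single-camera animal-tracking practice: a
static background reference is trained over the clip (per-pixel median,
robust as long as each pixel is fish-covered in fewer than half the
frames), each frame is compared to the reference by absolute difference
(so dark-on-light and light-on-dark animals are handled identically), an
optional 3x3 median filter suppresses salt-and-pepper sensor noise, the
difference image is binarized at a fixed threshold, and 8-connected
components above a minimum area become candidate detections.

Coordinate convention: x runs rightward along columns, y downward along
rows, pixel centers at integer coordinates. Centroids are unweighted
means of member pixel coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: default binarization threshold on |frame - reference|, intensity units
DEFAULT_DIFF_THRESHOLD = 30.0
#: default minimum blob area in pixels
DEFAULT_MIN_AREA = 20

# 8-connectivity structuring element for component labeling
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class FrameStack:
    """Ordered grayscale frames with shared geometry and frame period.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Pixel intensities in 0-255.
    frame_period_s : float
        Time between consecutive frames, seconds.
    """

    frames: np.ndarray
    frame_period_s: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, height, width), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a FrameStack needs at least one frame")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height_px(self) -> int:
        return self.frames.shape[1]

    @property
    def width_px(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class BackgroundModel:
    """Per-pixel reference image of the empty scene plus difference threshold."""

    reference: np.ndarray
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.reference.ndim != 2:
            raise ValueError("reference must be a 2-D pixel grid")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be positive")


@dataclass(frozen=True)
class Detection:
    """One blob in one frame: centroid (pixel coordinates) and area."""

    frame_index: int
    centroid_x: float
    centroid_y: float
    area_px: int

    @property
    def xy(self) -> tuple[float, float]:
        return (self.centroid_x, self.centroid_y)


def centered_crop_offsets(width: int, height: int, side: int) -> tuple[int, int]:
    """Offsets (x0, y0) of the centered ``side x side`` window."""
    if side > width or side > height:
        raise ValueError(f"side {side} exceeds frame {width}x{height}")
    return (width - side) // 2, (height - side) // 2


def crop_frames(stack: FrameStack, x0: int, y0: int, side: int) -> FrameStack:
    """Crop every frame to the ``side x side`` window at (x0, y0).

    The coordinate origin of the returned stack is the crop corner:
    cropped pixel (0, 0) is original pixel (x0, y0). Downstream
    detections are therefore expressed in crop coordinates, matching
    the usual workflow of cropping a recording to the tank area before
    analysis.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if x0 < 0 or y0 < 0 or x0 + side > stack.width_px or y0 + side > stack.height_px:
        raise ValueError(
            f"crop window ({x0},{y0})+{side} outside {stack.width_px}x{stack.height_px} frame"
        )
    cropped = stack.frames[:, y0 : y0 + side, x0 : x0 + side]
    logger.info("cropped %d frames to %dx%d at (%d,%d)", stack.n_frames, side, side, x0, y0)
    return FrameStack(frames=cropped.copy(), frame_period_s=stack.frame_period_s)


def train_background(
    stack: FrameStack, diff_threshold: float = DEFAULT_DIFF_THRESHOLD
) -> BackgroundModel:
    """Train a background model as the per-pixel median across frames.

    The median is robust to moving objects: a pixel's reference value is
    correct whenever the animal covers that pixel in fewer than half the
    frames, which holds for freely swimming fish in any clip of
    realistic length.
    """
    if stack.n_frames < 3:
        raise ValueError(f"need at least 3 frames to train a background, got {stack.n_frames}")
    reference = np.median(stack.frames.astype(np.float64), axis=0)
    logger.info("trained background model on %d frames", stack.n_frames)
    return BackgroundModel(reference=reference, diff_threshold=diff_threshold)


def detect(
    frame: np.ndarray,
    model: BackgroundModel,
    min_area: int = DEFAULT_MIN_AREA,
    median_filter: bool = True,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect blobs in one frame by background subtraction.

    Pipeline: absolute difference against the reference; optional 3x3
    median filter; binarize at ``model.diff_threshold`` (>=); 8-connected
    component labeling; drop components smaller than ``min_area``;
    centroid as the unweighted mean of member pixel coordinates.
    Detections are sorted by (centroid_y, centroid_x).
    """
    frame = np.asarray(frame)
    if frame.shape != model.reference.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match reference {model.reference.shape}"
        )
    diff = np.abs(frame.astype(np.float64) - model.reference)
    if median_filter:
        diff = ndimage.median_filter(diff, size=3)
    mask = diff >= model.diff_threshold
    labels, n_labels = ndimage.label(mask, structure=_STRUCTURE_8)
    if n_labels == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    detections = []
    for lab in keep:
        rows, cols = np.nonzero(labels == lab)
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid_x=float(cols.mean()),
                centroid_y=float(rows.mean()),
                area_px=int(rows.size),
            )
        )
    detections.sort(key=lambda d: (d.centroid_y, d.centroid_x))
    return detections


def detect_stack(
    stack: FrameStack,
    model: BackgroundModel,
    min_area: int = DEFAULT_MIN_AREA,
    median_filter: bool = True,
) -> list[list[Detection]]:
    """Run :func:`detect` over every frame; returns one list per frame."""
    out = [
        detect(stack.frames[i], model, min_area=min_area,
               median_filter=median_filter, frame_index=i)
        for i in range(stack.n_frames)
    ]
    logger.info(
        "detected %d blobs over %d frames", sum(len(d) for d in out), stack.n_frames
    )
    return out
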