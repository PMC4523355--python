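"""Dynamic difference-image segmentation.

Moving individuals are isolated by subtracting, from each frame, a reference
frame a constant time offset later and thresholding the result.  Stationary
pixels — background heterogeneity, uneven illumination, immobile debris —
cancel exactly, which is why this approach is preferred over intensity
thresholding for dark-field recordings with messy backgrounds.  The cost is
a known bias: immobile individuals vanish, and an individual overlapping its
own position ``offset`` frames later is partially eroded.

Two difference modes are provided:

``signed`` (default)
    ``max(I_t − I_{t+offset}, 0)``.  For bright particles on a dark
    background this keeps only the particle's position at time *t*; the
    vacated/occupied position at *t + offset* subtracts to zero.  Per-frame
    detections then count each moving individual once.
``abs``
    ``|I_t − I_{t+offset}|``.  Both positions appear as blobs (the second is
    the "ghost blob"); useful diagnostically and for thresholding studies,
    but downstream counts treat each individual twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .video_io import FrameStack


@dataclass
class SegmentationParams:
    """Parameters of difference segmentation and particle size gating.

    offset
        Time offset of the reference frame, in frames (the reference
        default of 25 frames equals 1 s at 25 fps).
    threshold
        Gray-value cut in [1, 255]; a difference pixel is foreground iff its
        value is ``>= threshold``.
    min_area, max_area
        Particle size gate in px²; components outside the interval are
        discarded.
    diff_mode
        ``"signed"`` or ``"abs"`` (see module docstring).
    blur_sigma
        Optional Gaussian pre-blur (px) applied to the raw frames before
        subtraction; 0 disables it (the default — the reference behaviour
        is unfiltered).
    grey_source
        Image on which particle gray statistics are measured:
        ``"difference"`` (the analysed image) or ``"raw"``.
    """

    offset: int = 25
    threshold: int = 40
    min_area: float = 5.0
    max_area: float = 1e5
    diff_mode: str = "signed"
    blur_sigma: float = 0.0
    grey_source: str = "difference"

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError(f"offset must be >= 1 frame, got {self.offset}")
        if not (0 < self.threshold <= 255):
            raise ValueError(f"threshold must be in (0, 255], got {self.threshold}")
        if not (0 <= self.min_area < self.max_area):
            raise ValueError(
                f"need 0 <= min_area < max_area, got {self.min_area}, {self.max_area}"
            )
        if self.diff_mode not in ("signed", "abs"):
            raise ValueError(f"diff_mode must be 'signed' or 'abs', got {self.diff_mode}")
        if self.grey_source not in ("difference", "raw"):
            raise ValueError(
                f"grey_source must be 'difference' or 'raw', got {self.grey_source}"
            )


def difference_image(
    stack: FrameStack, offset: int, mode: str = "signed", blur_sigma: float = 0.0
) -> FrameStack:
    """Difference stack: frame *t* of the output pairs frames *t* and *t+offset*.

    Returns ``T − offset`` frames; output frame *t* corresponds to original
    frame index *t* (the earlier frame of the pair), so detections made on
    it are located at their time-*t* positions.
    """
    T = len(stack)
    if not (1 <= offset < T):
        raise ValueError(f"offset must be in [1, {T - 1}] for a {T}-frame stack, got {offset}")
    frames = stack.frames.astype(np.int16)
    if blur_sigma > 0:
        frames = np.stack(
            [ndimage.gaussian_filter(f.astype(np.float32), blur_sigma) for f in frames]
        ).astype(np.int16)
    diff = frames[:-offset] - frames[offset:]
    if mode == "signed":
        diff = np.clip(diff, 0, 255)
    elif mode == "abs":
        diff = np.abs(diff)
    else:
        raise ValueError(f"mode must be 'signed' or 'abs', got {mode}")
    return FrameStack(
        frames=diff.astype(np.uint8),
        fps=stack.fps,
        scale=stack.scale,
        source_name=stack.source_name,
    )


def binarize(diff: FrameStack, threshold: int) -> np.ndarray:
    """Boolean masks: a pixel is foreground iff its difference value >= threshold."""
    if not (0 < threshold <= 255):
        raise ValueError(f"threshold must be in (0, 255], got {threshold}")
    return diff.frames >= threshold


def check_threshold_values(
    stack: FrameStack,
    offset: int,
    candidate_thresholds: list[int],
    out_dir: str | Path,
    frame_index: int | None = None,
    mode: str = "signed",
) -> list[Path]:
    """Write one raw-vs-binarized side-by-side panel per candidate threshold.

    Segmentation thresholds must be validated by eye per experimental
    system; this helper renders, for each candidate, the raw frame next to
    the binarized difference frame so the user can pick a value that keeps
    individuals and drops background.  Returns the paths written
    (``<video-stem>_thr<value>.png``).
    """
    if not candidate_thresholds:
        raise ValueError("candidate_thresholds must contain at least one value")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diff = difference_image(stack, offset, mode=mode)
    if frame_index is None:
        frame_index = len(diff) // 2
    raw = stack.frames[frame_index]
    stem = stack.stem or "video"
    sep = np.full((raw.shape[0], 4), 128, dtype=np.uint8)
    written: list[Path] = []
    for thr in candidate_thresholds:
        mask = (diff.frames[frame_index] >= thr).astype(np.uint8) * 255
        panel = np.hstack([raw, sep, mask])
        path = out_dir / f"{stem}_thr{thr}.png"
        iio.imwrite(path, panel)
        written.append(path)
    return written
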