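"""Frame-stack I/O and file-name conventions.

A video is represented as a :class:`FrameStack`: an ordered array of 8-bit
grayscale frames together with the frame rate (frames per second) and the
spatial calibration (micrometres per pixel).  Both calibration values are
supplied by the user — AVI container metadata is not trusted.

Supported sources are AVI files (when an imageio video backend is available)
and directories of numbered PNG/TIFF frames (``<stem>_<number>.<ext>``),
which round-trip bit-exactly and are the recommended archival format.
The Hamamatsu ``.cxd`` format is recognised but not decoded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: extensions accepted as video files
ACCEPTED_VIDEO_EXTENSIONS = frozenset({".avi"})
#: recognised but undecodable (reported as non-conforming with a hint)
RECOGNIZED_UNSUPPORTED_EXTENSIONS = frozenset({".cxd"})
#: extensions accepted inside an image-sequence directory
SEQUENCE_EXTENSIONS = frozenset({".png", ".tif", ".tiff"})

_SEQ_NAME_RE = re.compile(r"^(?P<stem>.*?)_?(?P<num>\d+)$")

# ITU-R 601 luminance weights for colour input
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """Ordered grayscale frames with temporal and spatial calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W), uint8
        Frame pixel data; all frames share one geometry.
    fps : float
        Frame rate in frames per second (> 0).
    scale : float
        Micrometres per pixel (> 0).
    source_name : str
        Name of the originating file or directory (used as merge key and
        in output file names).
    """

    frames: np.ndarray
    fps: float
    scale: float
    source_name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {self.frames.dtype}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def stem(self) -> str:
        """Source name without extension (merge key for metadata tables)."""
        return Path(self.source_name).stem if self.source_name else ""


def check_video_file_names(directory: str | Path) -> list[str]:
    """Return the names of entries that do not conform to the accepted formats.

    Accepted entries are ``.avi`` files and subdirectories containing at
    least one PNG/TIFF frame.  ``.cxd`` files are recognised as a known
    microscopy format but are not decodable here, so they are reported as
    non-conforming.  An empty list means every entry conforms.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"video directory does not exist: {directory}")
    bad: list[str] = []
    for entry in sorted(directory.iterdir()):
        if entry.name.startswith("."):
            continue
        if entry.is_dir():
            has_frames = any(
                p.suffix.lower() in SEQUENCE_EXTENSIONS for p in entry.iterdir()
            )
            if not has_frames:
                bad.append(entry.name)
            continue
        ext = entry.suffix.lower()
        if ext in ACCEPTED_VIDEO_EXTENSIONS:
            continue
        # .cxd is recognised-but-unsupported; report it like any other
        # non-conforming file so callers can migrate those videos.
        bad.append(entry.name)
    return bad


def _to_grey_uint8(img: np.ndarray) -> np.ndarray:
    """Convert one frame to 8-bit grayscale (luminance for colour input)."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64) @ _LUMA
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 257.0
    return np.clip(np.round(np.asarray(arr, dtype=np.float64)), 0, 255).astype(np.uint8)


def _sequence_files(directory: Path) -> list[Path]:
    """Frame files of a sequence directory, sorted by numeric suffix."""
    keyed: list[tuple[int, str, Path]] = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() not in SEQUENCE_EXTENSIONS:
            continue
        m = _SEQ_NAME_RE.match(p.stem)
        num = int(m.group("num")) if m else 0
        keyed.append((num, p.name, p))
    keyed.sort()
    return [p for _, _, p in keyed]


def load_frames(path: str | Path, fps: float, scale: float) -> FrameStack:
    """Load a video file or an image-sequence directory as a :class:`FrameStack`.

    Parameters
    ----------
    path : path
        ``.avi`` file or a directory of numbered PNG/TIFF frames.
    fps, scale : float
        Temporal (Hz) and spatial (μm/px) calibration; supplied by the
        user because container metadata is unreliable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video source does not exist: {path}")
    if path.is_dir():
        files = _sequence_files(path)
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        frames = [_to_grey_uint8(iio.imread(f)) for f in files]
    else:
        ext = path.suffix.lower()
        if ext in RECOGNIZED_UNSUPPORTED_EXTENSIONS:
            raise ValueError(
                f"{path.name}: .cxd is recognised but cannot be decoded here; "
                "convert to AVI or a PNG sequence first"
            )
        try:
            raw = iio.imread(path)
        except Exception as exc:  # backend missing or unreadable file
            raise ValueError(
                f"could not decode {path.name}: {exc}. AVI decoding requires an "
                "imageio video backend (e.g. imageio-ffmpeg); PNG/TIFF sequences "
                "are always supported"
            ) from exc
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        frames = [_to_grey_uint8(f) for f in raw]
    if len(frames) < 2:
        raise ValueError(
            f"{path}: needs at least 2 frames (difference segmentation pairs "
            "each frame with a later reference frame)"
        )
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"{path}: frames have inconsistent shapes {sorted(shapes)}")
    return FrameStack(
        frames=np.stack(frames), fps=fps, scale=scale, source_name=path.name
    )


def save_frames(
    stack: FrameStack, path: str | Path, format: str = "png_sequence"
) -> Path:
    """Write a frame stack as a PNG sequence (bit-exact) or an AVI file.

    ``png_sequence`` creates ``path/`` containing ``<stem>_00000.png``, … and
    round-trips exactly through :func:`load_frames`.  ``avi`` requires an
    imageio video backend.
    """
    path = Path(path)
    if len(stack) == 0:
        raise ValueError("cannot save an empty frame stack")
    if format == "png_sequence":
        path.mkdir(parents=True, exist_ok=True)
        stem = stack.stem or "frames"
        for i, frame in enumerate(stack.frames):
            iio.imwrite(path / f"{stem}_{i:05d}.png", frame)
        return path
    if format == "avi":
        try:
            iio.imwrite(path, stack.frames, fps=stack.fps)
        except Exception as exc:
            raise ValueError(
                f"could not write AVI {path}: {exc}. Writing AVI requires an "
                "imageio video backend; use format='png_sequence' instead"
            ) from exc
        return path
    raise ValueError(f"unknown format {format!r}; use 'avi' or 'png_sequence'")
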