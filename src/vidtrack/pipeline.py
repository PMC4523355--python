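"""End-to-end orchestration: config, metadata merge, counting, overlays.

The full flow per video is: load frames → difference segmentation →
particle measurement → trajectory linking → per-trajectory summaries →
quality filter → by-frame counts, with all tables written as CSV and every
parameter echoed into a run manifest.  Abundance is counted by frame and
averaged over the frames that have a defined difference image, so an
individual whose trajectory was split by an occlusion is still counted once
per frame rather than once per fragment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import __version__
from .linking import LinkParams, build_trajectory_table, link_particles
from .morphology import locate_and_measure_particles
from .segmentation import SegmentationParams
from .trajectory_stats import filter_data, summarize_trajectories
from .video_io import FrameStack, check_video_file_names, load_frames

logger = logging.getLogger("vidtrack")


@dataclass
class FilterParams:
    """Trajectory quality-filter thresholds (μm, s, fraction, μm)."""

    min_net: float = 50.0
    min_duration: float = 0.2
    min_detection_rate: float = 0.8
    min_median_step: float = 2.0


@dataclass
class PipelineConfig:
    """Everything needed to process a directory of videos.

    Defaults are the reference values for 25 fps dark-field recordings:
    a 25-frame difference offset, link range 5 frames, max displacement
    20 px, and filter thresholds 50 μm / 0.2 s / 80% / 2 μm.
    """

    input_dir: str = "."
    output_dir: str = "out"
    description_file: str | None = None
    fps: float = 25.0
    scale: float = 1.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    linking: LinkParams = field(default_factory=LinkParams)
    filters: FilterParams = field(default_factory=FilterParams)
    overlays: bool = False
    overlay_mode: str = "label"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a TOML file with sections per module.

        Recognised sections: ``[video]`` (input_dir, output_dir,
        description_file, fps, scale, overlays, overlay_mode),
        ``[segmentation]``, ``[linking]`` and ``[filters]`` with the
        corresponding dataclass fields.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        video = raw.get("video", {})
        return cls(
            **{k: v for k, v in video.items()},
            segmentation=SegmentationParams(**raw.get("segmentation", {})),
            linking=LinkParams(**raw.get("linking", {})),
            filters=FilterParams(**raw.get("filters", {})),
        )

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d


def merge_data(
    table: pd.DataFrame, description: pd.DataFrame, key: str = "file"
) -> pd.DataFrame:
    """Left-join experiment metadata onto per-detection/trajectory rows.

    ``description`` must have a unique ``file`` column holding video stems;
    rows from videos not covered by the description are kept with missing
    metadata, and a warning names those videos.
    """
    if key not in description.columns:
        raise ValueError(f"description table has no '{key}' column")
    dup = description[key][description[key].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate {key} entries in description: {list(dup)}")
    if "video" not in table.columns:
        raise ValueError("table is missing the 'video' column")
    stems = table["video"].map(lambda v: Path(str(v)).stem)
    merged = table.copy()
    merged["_stem"] = stems
    merged = merged.merge(
        description.rename(columns={key: "_stem"}), on="_stem", how="left"
    ).drop(columns="_stem")
    missing = sorted(set(stems) - set(description[key]))
    if missing:
        warnings.warn(
            f"videos absent from the description file: {missing}", stacklevel=2
        )
    return merged


def count_per_frame(
    detections: pd.DataFrame, n_frames: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """By-frame counts of retained detections, averaged per video.

    ``count(t)`` is the number of detections on frame ``t``; the abundance
    of a video is the mean of ``count(t)`` over frames ``[0, n_frames)``
    (the range with a defined difference image).  Counting by frame keeps a
    single individual split into several trajectories from inflating the
    abundance.  Returns ``(abundance table, per-frame count table)``.
    """
    if detections.empty:
        return (
            pd.DataFrame(columns=["video", "abundance"]),
            pd.DataFrame(columns=["video", "frame", "count"]),
        )
    frames = np.arange(n_frames)
    ab_rows, count_rows = [], []
    for video, group in detections.groupby("video", sort=True):
        counts = (
            group["frame"].value_counts().reindex(frames, fill_value=0).sort_index()
        )
        ab_rows.append({"video": video, "abundance": float(counts.mean())})
        count_rows.append(
            pd.DataFrame({"video": video, "frame": frames, "count": counts.to_numpy()})
        )
    return pd.DataFrame(ab_rows), pd.concat(count_rows, ignore_index=True)


_PALETTE = [
    (230, 60, 60), (60, 160, 230), (90, 200, 90), (240, 180, 40),
    (190, 90, 220), (80, 220, 210), (240, 120, 180), (160, 160, 160),
]


def create_overlays(
    stack: FrameStack,
    table: pd.DataFrame,
    out_path: str | Path,
    mode: str = "label",
    color_by: str | None = None,
    fmt: str = "png_sequence",
) -> Path:
    """Render trajectory annotations over the video for visual validation.

    ``mode="label"`` writes each trajectory's id at its current position on
    each frame; ``mode="traj"`` draws the path so far as a polyline.  With
    ``color_by="predicted_species"`` (requires that column) each species
    gets a fixed palette colour.  The overlay covers the frames that have a
    defined difference image, i.e. ``max(frame)+1`` frames of the table's
    span; pass the full stack.
    """
    if mode not in ("label", "traj"):
        raise ValueError(f"mode must be 'label' or 'traj', got {mode}")
    videos = set(table["video"].astype(str).unique())
    if videos and stack.source_name not in videos:
        raise ValueError(
            f"table refers to {sorted(videos)} but stack is {stack.source_name!r}"
        )
    if color_by is not None and color_by not in table.columns:
        raise ValueError(f"color_by column {color_by!r} not in table")
    n_frames = int(table["frame"].max()) + 1 if len(table) else len(stack)
    species = sorted(table[color_by].dropna().unique()) if color_by else []
    color_of = {s: _PALETTE[i % len(_PALETTE)] for i, s in enumerate(species)}

    frames_rgb = []
    for t in range(n_frames):
        img = Image.fromarray(stack.frames[t]).convert("RGB")
        draw = ImageDraw.Draw(img)
        current = table[table["frame"] == t]
        for traj_id, rows in table[table["frame"] <= t].groupby("traj_id"):
            color = (255, 255, 0)
            if color_by:
                val = rows[color_by].iloc[-1]
                color = color_of.get(val, (255, 255, 255))
            if mode == "traj" and len(rows) > 1:
                pts = list(zip(rows["x"].astype(float), rows["y"].astype(float)))
                draw.line(pts, fill=color, width=1)
        for _, row in current.iterrows():
            color = (255, 255, 0)
            if color_by:
                color = color_of.get(row[color_by], (255, 255, 255))
            x, y = float(row["x"]), float(row["y"])
            if mode == "label":
                draw.text((x + 3, y + 3), str(row["traj_id"]), fill=color)
            draw.ellipse([x - 2, y - 2, x + 2, y + 2], outline=color)
        frames_rgb.append(np.asarray(img))

    out_path = Path(out_path)
    if fmt == "png_sequence":
        out_path.mkdir(parents=True, exist_ok=True)
        stem = stack.stem or "overlay"
        for i, frame in enumerate(frames_rgb):
            Image.fromarray(frame).save(out_path / f"{stem}_overlay_{i:05d}.png")
        return out_path
    if fmt == "avi":
        import imageio.v3 as iio

        try:
            iio.imwrite(out_path, np.stack(frames_rgb), fps=stack.fps)
        except Exception as exc:
            raise ValueError(
                f"could not write AVI overlay: {exc}; use fmt='png_sequence'"
            ) from exc
        return out_path
    raise ValueError(f"unknown overlay format {fmt!r}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Process every conforming video under ``config.input_dir``.

    Writes ``particles.csv``, ``trajectories.csv``, ``summaries.csv``,
    ``summaries_filtered.csv``, ``master.csv`` (metadata-merged filtered
    detections), ``counts.csv`` + ``counts_per_frame.csv`` and
    ``manifest.json`` into ``config.output_dir``.  Deterministic: identical
    inputs and config produce byte-identical CSVs.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bad = check_video_file_names(in_dir)
    if bad:
        logger.warning("skipping non-conforming entries: %s", bad)
    sources = [
        p
        for p in sorted(in_dir.iterdir())
        if p.name not in bad and not p.name.startswith(".")
    ]
    if not sources:
        raise ValueError(f"no usable videos in {in_dir}")

    description = None
    if config.description_file:
        description = pd.read_csv(config.description_file)

    particle_tables, traj_tables = [], []
    n_diff_frames: dict[str, int] = {}
    for src in sources:
        try:
            stack = load_frames(src, fps=config.fps, scale=config.scale)
            logger.info("%s: %d frames", src.name, len(stack))
            particles = locate_and_measure_particles(stack, config.segmentation)
            logger.info("%s: %d particles", src.name, len(particles))
            trajs = link_particles(particles, config.linking)
            table = build_trajectory_table(particles, trajs, config.fps, config.scale)
            logger.info(
                "%s: %d trajectories", src.name, sum(len(v) for v in trajs.values())
            )
            n_diff_frames[stack.source_name] = len(stack) - config.segmentation.offset
            particle_tables.append(particles)
            traj_tables.append(table)
            if config.overlays:
                create_overlays(
                    stack,
                    table,
                    out_dir / f"{stack.stem}_overlay",
                    mode=config.overlay_mode,
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on video {src.name}: {exc}") from exc

    particles = pd.concat(particle_tables, ignore_index=True)
    trajectories = pd.concat(traj_tables, ignore_index=True)
    summaries = summarize_trajectories(trajectories, config.fps, config.scale)
    filtered = filter_data(
        summaries,
        min_net=config.filters.min_net,
        min_duration=config.filters.min_duration,
        min_detection_rate=config.filters.min_detection_rate,
        min_median_step=config.filters.min_median_step,
    )
    retained = trajectories[trajectories["id"].isin(set(filtered["id"]))]
    master = merge_data(retained, description) if description is not None else retained
    n_frames = max(n_diff_frames.values()) if n_diff_frames else 0
    abundance, per_frame = count_per_frame(retained, n_frames)

    _write_csv(particles, out_dir / "particles.csv")
    _write_csv(trajectories, out_dir / "trajectories.csv")
    _write_csv(summaries, out_dir / "summaries.csv")
    _write_csv(filtered, out_dir / "summaries_filtered.csv")
    _write_csv(master, out_dir / "master.csv")
    _write_csv(abundance, out_dir / "counts.csv")
    _write_csv(per_frame, out_dir / "counts_per_frame.csv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2, sort_keys=True)
    return out_dir
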