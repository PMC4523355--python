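"""Synthetic dark-field-style videos with known ground truth.

The generator emulates the features of dark-field microscopy recordings
that matter to the analysis chain: bright ellipsoidal individuals on a dark,
heterogeneous background (static low-frequency gradient plus per-frame
pixel noise), species-specific size/shape/speed distributions, motion as a
correlated random walk (per-frame step length ~ truncated Normal, turning
angle ~ wrapped Normal around zero), an unrestricted viewing field
(individuals leave, and optionally enter, across the open boundary),
immobile debris, and stochastic per-frame detection dropout.

Every random draw comes from one seeded generator stream, so a given seed
reproduces the frame stack bit for bit.

Individuals are kept from overlapping by a simple avoidance rule (a step
that would bring two bodies closer than their summed semi-major axes plus a
margin is re-tried at sideways deflections, then reversed, then skipped) —
the generator models well-separated swimmers; occlusion handling downstream
is exercised by explicitly constructed fixtures rather than by chance
collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .video_io import FrameStack

#: ground-truth table columns
TRUTH_COLUMNS = [
    "frame", "individual", "traj_id", "species", "x", "y",
    "major", "minor", "angle", "visible",
]


@dataclass
class SpeciesSpec:
    """Trait distribution of one synthetic species.

    Sizes are in μm (converted with the video scale), speeds in μm/s,
    ``turning_sd`` in radians (SD of the wrapped-Normal turning angle; small
    values give persistent, nearly ballistic paths), ``intensity`` is the
    body gray value (must exceed the background).
    """

    name: str
    major_mean: float = 15.0
    major_sd: float = 1.5
    aspect_mean: float = 2.0
    aspect_sd: float = 0.2
    speed_mean: float = 75.0
    speed_sd: float = 15.0
    turning_sd: float = 0.5
    intensity: int = 200

    def __post_init__(self) -> None:
        for name in ("major_mean", "aspect_mean", "speed_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.intensity <= 255):
            raise ValueError(f"intensity must be in (0, 255], got {self.intensity}")


@dataclass
class GroundTruth:
    """Per-frame truth of a synthetic video.

    ``table`` has one row per (frame, individual) while the individual is
    in-field; ``visible`` is False on frames where detection dropout
    suppressed the rendering.  ``angle`` uses the same convention as the
    morphology module (degrees in [0, 180), +x axis, y up).
    """

    table: pd.DataFrame
    debris: pd.DataFrame
    n_per_species: dict[str, int]
    field_shape: tuple[int, int]
    fps: float
    scale: float

    def mean_count(self, n_frames: int | None = None, visible_only: bool = True) -> float:
        """Mean number of in-field individuals over frames [0, n_frames)."""
        t = self.table
        if n_frames is not None:
            t = t[t["frame"] < n_frames]
        if visible_only:
            t = t[t["visible"]]
        n = n_frames if n_frames is not None else int(self.table["frame"].max()) + 1
        return len(t) / n if n else 0.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > low:
            return v
    return max(mean, low + 1e-6)


@dataclass
class _Individual:
    ident: int
    species: int
    x: float
    y: float
    heading: float
    major_px: float
    minor_px: float
    speed_px: float  # mean step per frame, px
    speed_sd_px: float
    turning_sd: float
    active: bool = True


def _min_sep(a: _Individual, b: _Individual, margin: float) -> float:
    return (a.major_px + b.major_px) / 2.0 + margin


def _collides(ind: _Individual, x: float, y: float, others, debris_xy, margin: float) -> bool:
    for other in others:
        if other is ind or not other.active:
            continue
        if np.hypot(x - other.x, y - other.y) < _min_sep(ind, other, margin):
            return True
    for dx, dy, dmaj in debris_xy:
        if np.hypot(x - dx, y - dy) < (ind.major_px + dmaj) / 2.0 + margin:
            return True
    return False


def simulate_video(
    species: list[SpeciesSpec],
    n_per_species: int | list[int],
    n_frames: int,
    fps: float = 25.0,
    scale: float = 1.0,
    field: tuple[int, int] = (512, 512),
    bg_mean: float = 20.0,
    bg_gradient: float = 25.0,
    noise_sd: float = 3.0,
    dropout_rate: float = 0.0,
    n_debris: int = 5,
    entry_rate: float = 0.0,
    sep_margin: float = 4.0,
    edge_margin: float = 64.0,
    seed: int = 0,
    source_name: str = "synthetic.avi",
) -> tuple[FrameStack, GroundTruth]:
    """Render a synthetic video and its ground truth.

    Parameters mirror the study conditions the generator emulates: species
    trait specs, the number of individuals per species, frame count,
    temporal/spatial calibration, background model (mean level + amplitude
    of a static low-frequency gradient + per-frame Gaussian pixel noise
    SD), per-frame detection ``dropout_rate``, a count of immobile debris
    particles, and a Poisson ``entry_rate`` (individuals per frame) of new
    arrivals across the open boundary.  Individuals whose centre leaves the
    field exit permanently; initial individuals are placed at least
    ``edge_margin`` px from the boundary, later entrants appear on it.

    Returns the rendered :class:`FrameStack` and a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    H, W = field
    if isinstance(n_per_species, int):
        counts = [n_per_species] * len(species)
    else:
        counts = list(n_per_species)
        if len(counts) != len(species):
            raise ValueError("n_per_species must match the species list")
    max_major_px = max((sp.major_mean + 4 * sp.major_sd) / scale for sp in species) if species else 0.0
    if species and (max_major_px * 3 > min(H, W)):
        raise ValueError(
            f"field {field} too small for bodies up to {max_major_px:.0f} px"
        )

    # static background: mean + low-frequency gradient; per-frame noise added later
    yy, xx = np.mgrid[0:H, 0:W]
    background = (
        bg_mean
        + bg_gradient * 0.5 * (1 + np.sin(2 * np.pi * xx / W) * np.cos(2 * np.pi * yy / H))
    )

    # debris: immobile ellipses with intensities in the particle range
    debris_rows = []
    for _ in range(n_debris):
        dmaj = rng.uniform(4, 12)
        debris_rows.append(
            {
                "x": rng.uniform(0, W),
                "y": rng.uniform(0, H),
                "major": dmaj,
                "minor": dmaj / rng.uniform(1.0, 2.0),
                "angle": rng.uniform(0, 180),
                "intensity": int(rng.integers(120, 220)),
            }
        )
    debris = pd.DataFrame(debris_rows, columns=["x", "y", "major", "minor", "angle", "intensity"])
    debris_xy = [(r["x"], r["y"], r["major"]) for r in debris_rows]

    individuals: list[_Individual] = []
    next_id = 0

    def make_individual(si: int, at_edge: bool) -> _Individual | None:
        nonlocal next_id
        sp = species[si]
        major_px = _truncated_normal(rng, sp.major_mean, sp.major_sd, 2.0) / scale
        aspect = _truncated_normal(rng, sp.aspect_mean, sp.aspect_sd, 1.05)
        ind = _Individual(
            ident=next_id,
            species=si,
            x=0.0,
            y=0.0,
            heading=rng.uniform(-np.pi, np.pi),
            major_px=major_px,
            minor_px=major_px / aspect,
            speed_px=sp.speed_mean / (fps * scale),
            speed_sd_px=sp.speed_sd / (fps * scale),
            turning_sd=sp.turning_sd,
        )
        margin_px = major_px / 2 + 1
        for _ in range(200):
            if at_edge:
                side = rng.integers(4)
                pos = rng.uniform(margin_px, W - margin_px if side < 2 else H - margin_px)
                if side == 0:
                    x, y = pos, margin_px
                elif side == 1:
                    x, y = pos, H - margin_px
                elif side == 2:
                    x, y = margin_px, pos
                else:
                    x, y = W - margin_px, pos
            else:
                # initial placement stays clear of the open boundary so the
                # population is not depleted in the first moments
                m = margin_px + min(edge_margin, (min(H, W) - 2 * margin_px) / 4)
                x = rng.uniform(m, W - m)
                y = rng.uniform(m, H - m)
            if not _collides(ind, x, y, individuals, debris_xy, sep_margin):
                ind.x, ind.y = x, y
                next_id += 1
                return ind
        return None  # no free spot found; skip this arrival

    for si in range(len(species)):
        for _ in range(counts[si]):
            ind = make_individual(si, at_edge=False)
            if ind is None:
                raise ValueError(
                    f"field {field} too crowded to place {counts[si]} "
                    f"individuals of species {species[si].name}"
                )
            individuals.append(ind)

    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    truth_rows: list[dict] = []
    for t in range(n_frames):
        img = background + rng.normal(0.0, noise_sd, size=(H, W))
        for d in debris_rows:
            rr, cc = draw_ellipse(
                d["y"], d["x"], d["minor"] / 2, d["major"] / 2,
                shape=(H, W), rotation=np.deg2rad(-d["angle"]),
            )
            img[rr, cc] = np.maximum(img[rr, cc], d["intensity"])
        for ind in individuals:
            if not ind.active:
                continue
            visible = rng.random() >= dropout_rate
            if visible:
                rr, cc = draw_ellipse(
                    ind.y, ind.x, ind.minor_px / 2, ind.major_px / 2,
                    shape=(H, W), rotation=-ind.heading,
                )
                intensity = species[ind.species].intensity
                img[rr, cc] = np.maximum(img[rr, cc], intensity)
            truth_rows.append(
                {
                    "frame": t,
                    "individual": ind.ident,
                    "traj_id": ind.ident,
                    "species": species[ind.species].name,
                    "x": ind.x,
                    "y": ind.y,
                    "major": ind.major_px * scale,
                    "minor": ind.minor_px * scale,
                    "angle": (-np.degrees(ind.heading)) % 180.0,
                    "visible": visible,
                }
            )
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)

        # advance the walk (state now describes frame t+1)
        for ind in individuals:
            if not ind.active:
                continue
            ind.heading = float(
                np.angle(np.exp(1j * (ind.heading + rng.normal(0.0, ind.turning_sd))))
            )
            step = max(rng.normal(ind.speed_px, ind.speed_sd_px), 0.0)
            # avoidance: deflect sideways first so near misses slide past
            # each other instead of ping-ponging head-on
            for deflect in (0.0, np.pi / 3, -np.pi / 3, 2 * np.pi / 3,
                            -2 * np.pi / 3, np.pi):
                heading = ind.heading + deflect
                nx = ind.x + step * np.cos(heading)
                ny = ind.y + step * np.sin(heading)
                if not _collides(ind, nx, ny, individuals, debris_xy, sep_margin):
                    ind.heading = float(np.angle(np.exp(1j * heading)))
                    ind.x, ind.y = nx, ny
                    break
            if not (0 <= ind.x < W and 0 <= ind.y < H):
                ind.active = False  # exited the open boundary
        if entry_rate > 0:
            for _ in range(rng.poisson(entry_rate)):
                si = int(rng.integers(len(species)))
                ind = make_individual(si, at_edge=True)
                if ind is not None:
                    individuals.append(ind)

    stack = FrameStack(frames=frames, fps=fps, scale=scale, source_name=source_name)
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        debris=debris,
        n_per_species={sp.name: c for sp, c in zip(species, counts)},
        field_shape=(H, W),
        fps=fps,
        scale=scale,
    )
    return stack, truth


@dataclass
class TrackingScore:
    """Agreement between pipeline output and synthetic ground truth."""

    true_mean_count: float
    est_mean_count: float
    count_rel_error: float
    position_rmse: float
    identity_f1: float
    major_recovery_ratio: float
    n_matched: int
    n_detections: int


def _pair_count(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2.0))


def score_against_truth(
    detections: pd.DataFrame,
    truth: GroundTruth,
    n_frames: int,
    match_radius: float = 10.0,
) -> TrackingScore:
    """Score detections (with ``traj_id``) against ground truth.

    Detections are matched to visible truth rows frame by frame, greedily
    by increasing distance within ``match_radius`` px.  Reports the by-frame
    count agreement, the position RMSE over matches, the trajectory
    identity F1 (pair-counting: two matched detections co-assigned in a
    predicted trajectory iff co-assigned in truth), and the median ratio of
    measured to true major-axis length.
    """
    tt = truth.table[(truth.table["visible"]) & (truth.table["frame"] < n_frames)]
    true_mean = len(tt) / n_frames if n_frames else 0.0
    det = detections[detections["frame"] < n_frames]
    est_mean = len(det) / n_frames if n_frames else 0.0

    matches: list[tuple[int, int]] = []  # (truth row pos, det row pos)
    sq_err: list[float] = []
    for t, dgrp in det.groupby("frame"):
        tgrp = tt[tt["frame"] == t]
        if tgrp.empty:
            continue
        tx = tgrp["x"].to_numpy()
        ty = tgrp["y"].to_numpy()
        dx = dgrp["x"].to_numpy()
        dy = dgrp["y"].to_numpy()
        dist = np.hypot(tx[:, None] - dx[None, :], ty[:, None] - dy[None, :])
        pairs = np.argwhere(dist <= match_radius)
        order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
        used_t: set[int] = set()
        used_d: set[int] = set()
        for a, b in pairs[order]:
            if a in used_t or b in used_d:
                continue
            used_t.add(int(a))
            used_d.add(int(b))
            matches.append((tgrp.index[a], dgrp.index[b]))
            sq_err.append(float(dist[a, b] ** 2))

    if matches:
        t_idx = [m[0] for m in matches]
        d_idx = [m[1] for m in matches]
        true_ids = truth.table.loc[t_idx, "traj_id"].to_numpy()
        pred_ids = detections.loc[d_idx, "id"].astype(str).to_numpy()
        both = pd.MultiIndex.from_arrays([true_ids, pred_ids])
        tp = _pair_count(both.to_numpy())
        p_pairs = _pair_count(pred_ids)
        t_pairs = _pair_count(true_ids)
        precision = tp / p_pairs if p_pairs else 1.0
        recall = tp / t_pairs if t_pairs else 1.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rmse = float(np.sqrt(np.mean(sq_err)))
        if "major" in detections.columns:
            ratio = float(
                np.median(
                    detections.loc[d_idx, "major"].to_numpy()
                    / truth.table.loc[t_idx, "major"].to_numpy()
                )
            )
        else:
            ratio = np.nan
    else:
        f1, rmse, ratio = 0.0, np.nan, np.nan

    return TrackingScore(
        true_mean_count=true_mean,
        est_mean_count=est_mean,
        count_rel_error=abs(est_mean - true_mean) / true_mean if true_mean else np.nan,
        position_rmse=rmse,
        identity_f1=f1,
        major_recovery_ratio=ratio,
        n_matched=len(matches),
        n_detections=len(det),
    )
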