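"""Trajectory reconstruction by stage-wise optimal assignment with gap closing.

Detections are linked frame by frame: at each frame the detections are
matched to the currently active tracks by minimum total squared per-frame
displacement (Hungarian assignment with a null option on both sides), where
a track stays "active" until its last detection is more than ``link_range``
frames in the past.  A link spanning ``g`` frames is allowed a displacement
of ``g · max_disp`` (linear gap allowance; a fixed allowance is available)
and costs ``d²/g`` — the squared displacement averaged per frame, so that
a gap is paid for the way a diffusing particle would pay for it — while
the null option costs ``max_disp²`` on either side.  Under this model a
link at moderate per-frame displacement is always cheaper than leaving
both of its ends unmatched, and a track that lost its particle (e.g. it
left the field) cannot outbid the rightful owner of a nearby detection.

Occlusions are handled conservatively: when two tracks compete for one
detection the cheaper link wins (ties go to the older track) and the loser
is simply left unmatched — if nothing claims it within the link range it
terminates, and no attempt is ever made to recombine the fragments.  Every
detection ends up in exactly one trajectory; a detection nothing claims
starts a new (possibly length-1) trajectory.

Per-step movement metrics are computed for each consecutive detection pair:
step length (μm), absolute angle of the displacement vector, turning angle
(wrapped difference of consecutive absolute angles, defined from the second
step on), net squared displacement from the trajectory start (μm²) and gross
(cumulative) path length (μm).  Angles are radians internally; output tables
carry degree columns alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

_INFEASIBLE = 1e12
# deterministic preference for the older track among exactly-tied links
_TIE_EPS = 1e-7


@dataclass
class LinkParams:
    """Linking parameters.

    link_range
        Maximum frame gap L over which a missing detection may be bridged
        (default: 5 frames).
    max_disp
        Maximum displacement (px) between two successive frames
        (default: 20 px).
    gap_scaling
        ``"linear"``: a g-frame link is allowed g·max_disp of displacement;
        ``"fixed"``: max_disp regardless of gap.
    """

    link_range: int = 5
    max_disp: float = 20.0
    gap_scaling: str = "linear"

    def __post_init__(self) -> None:
        if self.link_range < 1:
            raise ValueError(f"link_range must be >= 1, got {self.link_range}")
        if self.max_disp <= 0:
            raise ValueError(f"max_disp must be > 0, got {self.max_disp}")
        if self.gap_scaling not in ("linear", "fixed"):
            raise ValueError(
                f"gap_scaling must be 'linear' or 'fixed', got {self.gap_scaling}"
            )

    def allowed(self, gap: int) -> float:
        """Displacement allowance for a link spanning ``gap`` frames."""
        return self.max_disp * gap if self.gap_scaling == "linear" else self.max_disp


@dataclass
class Trajectory:
    """One reconstructed trajectory within a single video."""

    traj_id: int
    video: str
    frames: np.ndarray  # strictly increasing, 0-based
    x: np.ndarray  # px
    y: np.ndarray  # px
    det_rows: np.ndarray  # row indices into the particle table
    metrics: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.frames)


REQUIRED_COLUMNS = ("video", "frame", "x", "y")


def _link_positions(
    frames: np.ndarray, xs: np.ndarray, ys: np.ndarray, params: LinkParams
) -> tuple[list[list[int]], list[float]]:
    """Core linker on one video's detections.

    Returns (tracks, stage_costs): tracks as lists of detection indices,
    and the realised assignment cost of each frame stage (squared linked
    displacements plus null costs of unmatched tracks/detections) —
    exposed so tests can compare against exhaustive enumeration.
    """
    order = np.lexsort((ys, xs, frames))
    tracks: list[list[int]] = []
    last_frame: list[int] = []
    last_pos: list[tuple[float, float]] = []
    stage_costs: list[float] = []

    for t in np.unique(frames):
        det_idx = [int(i) for i in order if frames[i] == t]
        cand = [
            k
            for k in range(len(tracks))
            if 0 < t - last_frame[k] <= params.link_range
        ]
        n_c, n_d = len(cand), len(det_idx)
        matched_dets: set[int] = set()
        if n_c and n_d:
            C = np.full((n_c + n_d, n_d + n_c), _INFEASIBLE)
            for a, k in enumerate(cand):
                gap = int(t - last_frame[k])
                allow = params.allowed(gap)
                px, py = last_pos[k]
                for b, i in enumerate(det_idx):
                    d2 = (xs[i] - px) ** 2 + (ys[i] - py) ** 2
                    if d2 <= allow**2:
                        C[a, b] = d2 / gap + _TIE_EPS * a
                C[a, n_d + a] = params.max_disp**2  # track goes unmatched this stage
            for b in range(n_d):
                C[n_c + b, b] = params.max_disp**2  # detection starts a new track
            C[n_c:, n_d:] = 0.0
            rows, cols = linear_sum_assignment(C)
            cost = 0.0
            for a, b in zip(rows, cols):
                if a < n_c and b < n_d and C[a, b] < _INFEASIBLE:
                    k, i = cand[a], det_idx[b]
                    tracks[k].append(i)
                    last_frame[k] = int(t)
                    last_pos[k] = (float(xs[i]), float(ys[i]))
                    matched_dets.add(i)
                    cost += C[a, b] - _TIE_EPS * a
                elif a < n_c and b >= n_d:
                    cost += C[a, b]
                elif a >= n_c and b < n_d:
                    cost += C[a, b]
            stage_costs.append(cost)
        elif n_c:
            stage_costs.append(params.max_disp**2 * n_c)
        elif n_d:
            stage_costs.append(params.max_disp**2 * n_d)
        else:
            stage_costs.append(0.0)
        for i in det_idx:
            if i not in matched_dets:
                tracks.append([i])
                last_frame.append(int(t))
                last_pos.append((float(xs[i]), float(ys[i])))
    return tracks, stage_costs


def link_particles(
    particles: pd.DataFrame, params: LinkParams | None = None
) -> dict[str, list[Trajectory]]:
    """Partition a particle table into trajectories, per video.

    Linking uses x/y positions only.  Trajectory ids are assigned in
    deterministic order (birth frame, then first x, then first y) and are
    unique within each video.
    """
    if params is None:
        params = LinkParams()
    missing = [c for c in REQUIRED_COLUMNS if c not in particles.columns]
    if missing:
        raise ValueError(f"particle table is missing required columns: {missing}")
    out: dict[str, list[Trajectory]] = {}
    for video, group in particles.groupby("video", sort=True):
        frames = group["frame"].to_numpy()
        xs = group["x"].to_numpy(dtype=float)
        ys = group["y"].to_numpy(dtype=float)
        row_index = group.index.to_numpy()
        track_idx, _ = _link_positions(frames, xs, ys, params)
        keyed = sorted(
            track_idx,
            key=lambda tr: (int(frames[tr[0]]), float(xs[tr[0]]), float(ys[tr[0]])),
        )
        trajs = []
        for tid, tr in enumerate(keyed):
            tr = sorted(tr, key=lambda i: int(frames[i]))
            trajs.append(
                Trajectory(
                    traj_id=tid,
                    video=str(video),
                    frames=frames[tr].astype(int),
                    x=xs[tr],
                    y=ys[tr],
                    det_rows=row_index[tr],
                )
            )
        out[str(video)] = trajs
    return out


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (−π, π]."""
    wrapped = -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)
    return wrapped


def compute_step_metrics(traj: Trajectory, fps: float, scale: float) -> Trajectory:
    """Fill per-detection movement metrics on a trajectory (in place).

    The metrics frame has one row per detection: ``step_length`` (μm, NaN on
    the first detection), ``abs_angle`` and ``turning_angle`` (radians; a
    zero-length step has no direction, so its angle and any turning angle
    involving it are NaN), ``nsd`` (μm², from the first detection) and
    ``gross`` (cumulative path length, μm).
    """
    n = len(traj)
    dx = np.diff(traj.x) * scale
    dy = np.diff(traj.y) * scale
    step = np.hypot(dx, dy)
    with np.errstate(invalid="ignore"):
        ang = np.where(step > 0, np.arctan2(-dy, dx), np.nan)
    turning = np.full(n, np.nan)
    if n > 2:
        turn = np.asarray(wrap_angle(ang[1:] - ang[:-1]))
        turn[np.isnan(ang[1:]) | np.isnan(ang[:-1])] = np.nan
        turning[2:] = turn
    nsd = ((traj.x - traj.x[0]) ** 2 + (traj.y - traj.y[0]) ** 2) * scale**2
    gross = np.concatenate([[0.0], np.cumsum(step)])
    traj.metrics = pd.DataFrame(
        {
            "step_length": np.concatenate([[np.nan], step]),
            "abs_angle": np.concatenate([[np.nan], ang]),
            "turning_angle": turning,
            "nsd": nsd,
            "gross": gross,
        }
    )
    return traj


def build_trajectory_table(
    particles: pd.DataFrame,
    trajectories: dict[str, list[Trajectory]],
    fps: float,
    scale: float,
) -> pd.DataFrame:
    """Join trajectory ids and step metrics onto the particle rows.

    Produces the long-format trajectory table: one row per linked detection
    with ``traj_id``, the composite ``id`` (``<video>-<traj_id>``), the
    movement metrics (radians plus ``*_deg`` convenience columns) and all
    morphology columns of the input.
    """
    pieces = []
    for video, trajs in trajectories.items():
        for traj in trajs:
            if traj.metrics is None:
                compute_step_metrics(traj, fps, scale)
            part = particles.loc[traj.det_rows].copy()
            part["traj_id"] = traj.traj_id
            part["id"] = f"{video}-{traj.traj_id}"
            met = traj.metrics.set_index(part.index)
            for col in ("step_length", "abs_angle", "turning_angle", "nsd", "gross"):
                part[col] = met[col]
            pieces.append(part)
    if not pieces:
        cols = list(particles.columns) + [
            "traj_id", "id", "step_length", "abs_angle", "turning_angle", "nsd",
            "gross", "abs_angle_deg", "turning_angle_deg",
        ]
        return pd.DataFrame(columns=cols)
    table = pd.concat(pieces)
    table["abs_angle_deg"] = np.degrees(table["abs_angle"])
    table["turning_angle_deg"] = np.degrees(table["turning_angle"])
    return table.sort_values(["video", "traj_id", "frame"], kind="stable").reset_index(
        drop=True
    )
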