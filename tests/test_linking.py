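import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vidtrack import LinkParams, build_trajectory_table, compute_step_metrics, link_particles
from vidtrack.linking import Trajectory, _link_positions, wrap_angle
from oracle_linking import brute_force_link


def det_table(rows, video="v.avi"):
    """rows: (frame, x, y)"""
    return pd.DataFrame(
        {
            "video": video,
            "frame": [r[0] for r in rows],
            "x": [r[1] for r in rows],
            "y": [r[2] for r in rows],
        }
    )


def co_membership(trajs, table):
    """frozenset of frozensets of (frame, x, y) per trajectory."""
    out = []
    for tr in trajs:
        out.append(frozenset(zip(tr.frames, tr.x, tr.y)))
    return frozenset(out)


class TestLinkParticles:
    def test_two_separated_movers_recovered(self):
        rows = []
        for t in range(10):
            rows.append((t, 10.0 + 3 * t, 10.0))
            rows.append((t, 210.0 - 3 * t, 10.0))
        trajs = link_particles(det_table(rows), LinkParams(max_disp=20))["v.avi"]
        assert len(trajs) == 2
        for tr in trajs:
            assert len(tr) == 10
            # each trajectory moves monotonically: it stayed on one particle
            assert np.all(np.abs(np.diff(tr.x)) == 3.0)

    def test_gap_closed_within_link_range(self):
        rows = [(0, 10, 10), (1, 13, 10), (3, 19, 10), (4, 22, 10)]
        trajs = link_particles(det_table(rows), LinkParams(link_range=2, max_disp=20))[
            "v.avi"
        ]
        assert len(trajs) == 1
        assert list(trajs[0].frames) == [0, 1, 3, 4]

    def test_gap_beyond_link_range_splits(self):
        rows = [(0, 10, 10), (1, 13, 10), (3, 19, 10), (4, 22, 10)]
        trajs = link_particles(det_table(rows), LinkParams(link_range=1, max_disp=20))[
            "v.avi"
        ]
        assert sorted(len(t) for t in trajs) == [2, 2]

    def test_displacement_above_maximum_never_linked(self):
        rows = [(0, 10, 10), (1, 50, 10)]
        trajs = link_particles(det_table(rows), LinkParams(max_disp=20))["v.avi"]
        assert len(trajs) == 2

    def test_occlusion_terminates_loser_without_recombination(self):
        # two particles converge onto one shared detection, then separate:
        # the winner continues, the loser's later detections start a new id
        rows = [
            (0, 0.0, 0.0), (0, 40.0, 0.0),
            (1, 10.0, 0.0), (1, 30.0, 0.0),
            (2, 20.0, 0.0),          # single merged detection
            (3, 10.0, 0.0), (3, 30.0, 0.0),
            (4, 0.0, 0.0), (4, 40.0, 0.0),
        ]
        trajs = link_particles(det_table(rows), LinkParams(link_range=1, max_disp=15))[
            "v.avi"
        ]
        sizes = sorted(len(t) for t in trajs)
        assert sum(sizes) == 9  # conservation
        assert len(trajs) == 3  # one winner through the merge, loser split in two

    def test_missing_columns_named_in_error(self):
        with pytest.raises(ValueError, match="x"):
            link_particles(pd.DataFrame({"video": [], "frame": [], "y": []}))

    def test_singleton_detections_form_length_one_trajectories(self):
        rows = [(0, 10, 10), (5, 300, 300)]
        trajs = link_particles(det_table(rows), LinkParams(link_range=2))["v.avi"]
        assert sorted(len(t) for t in trajs) == [1, 1]

    def test_row_order_within_frames_is_irrelevant(self, rng):
        rows = []
        for t in range(6):
            for p in range(4):
                rows.append((t, 50.0 * p + 2.0 * t, 30.0 + rng.normal(0, 2)))
        base = det_table(rows)
        shuffled = base.sample(frac=1, random_state=7).reset_index(drop=True)
        t1 = link_particles(base, LinkParams())["v.avi"]
        t2 = link_particles(shuffled, LinkParams())["v.avi"]
        assert co_membership(t1, base) == co_membership(t2, shuffled)

    def test_conservation_on_random_input(self, rng):
        rows = [
            (int(t), float(x), float(y))
            for t, x, y in zip(
                rng.integers(0, 12, 120), rng.uniform(0, 200, 120), rng.uniform(0, 200, 120)
            )
        ]
        table = det_table(rows)
        trajs = link_particles(table, LinkParams())["v.avi"]
        assert sum(len(t) for t in trajs) == len(table)
        all_rows = np.concatenate([t.det_rows for t in trajs])
        assert sorted(all_rows) == list(range(len(table)))

    def test_traj_ids_ordered_by_birth(self):
        rows = [(0, 100, 5), (0, 10, 5), (2, 300, 300)]
        trajs = link_particles(det_table(rows), LinkParams(max_disp=5))["v.avi"]
        births = [(t.traj_id, t.frames[0], t.x[0]) for t in trajs]
        assert births == sorted(births)
        assert births[0][2] == 10  # same birth frame: lower x first


class TestLinkerMatchesExhaustiveOracle:
    @pytest.mark.parametrize("n_particles,n_frames", [(2, 4), (3, 6), (4, 5)])
    def test_stage_costs_equal_enumeration_optimum(self, n_particles, n_frames):
        params = LinkParams(link_range=2, max_disp=25)
        rng = np.random.default_rng(n_particles * 100 + n_frames)
        for _ in range(12):
            frames, xs, ys = [], [], []
            pos = rng.uniform(20, 180, (n_particles, 2))
            for t in range(n_frames):
                pos = pos + rng.uniform(-8, 8, pos.shape)
                for p in range(n_particles):
                    if rng.random() < 0.25:
                        continue  # dropout creates gaps and new tracks
                    frames.append(t)
                    xs.append(pos[p, 0])
                    ys.append(pos[p, 1])
            if not frames:
                continue
            frames = np.array(frames)
            xs = np.array(xs)
            ys = np.array(ys)
            _, got = _link_positions(frames, xs, ys, params)
            _, want = brute_force_link(frames, xs, ys, params)
            assert len(got) == len(want)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-4)


class TestStepMetrics:
    def _traj(self, pts, frames=None):
        pts = np.asarray(pts, float)
        frames = np.arange(len(pts)) if frames is None else np.asarray(frames)
        return Trajectory(
            traj_id=0, video="v", frames=frames, x=pts[:, 0], y=pts[:, 1],
            det_rows=np.arange(len(pts)),
        )

    def test_three_four_five_triangle(self):
        tr = compute_step_metrics(self._traj([(0, 0), (3, 4)]), fps=25, scale=1.0)
        assert tr.metrics["step_length"].iloc[1] == pytest.approx(5.0)

    def test_collinear_steps_have_zero_turning(self):
        pts = [(i * 2.0, i * 1.0) for i in range(6)]
        tr = compute_step_metrics(self._traj(pts), fps=25, scale=1.0)
        turns = tr.metrics["turning_angle"].to_numpy()
        assert np.isnan(turns[:2]).all()
        np.testing.assert_allclose(turns[2:], 0.0, atol=1e-12)

    def test_ballistic_nsd_equals_gross_squared(self):
        v, k = 3.0, 8
        pts = [(i * v, 0.0) for i in range(k + 1)]
        tr = compute_step_metrics(self._traj(pts), fps=25, scale=1.0)
        m = tr.metrics
        assert m["nsd"].iloc[-1] == pytest.approx((k * v) ** 2)
        assert m["gross"].iloc[-1] == pytest.approx(k * v)
        np.testing.assert_allclose(m["nsd"], m["gross"] ** 2, rtol=1e-12)

    def test_scale_converts_to_micrometres(self):
        tr = compute_step_metrics(self._traj([(0, 0), (3, 4)]), fps=25, scale=2.5)
        assert tr.metrics["step_length"].iloc[1] == pytest.approx(12.5)
        assert tr.metrics["nsd"].iloc[1] == pytest.approx(12.5**2)

    def test_zero_length_step_has_undefined_angles(self):
        pts = [(0, 0), (1, 0), (1, 0), (2, 0)]
        tr = compute_step_metrics(self._traj(pts), fps=25, scale=1.0)
        m = tr.metrics
        assert np.isnan(m["abs_angle"].iloc[2])
        assert np.isnan(m["turning_angle"].iloc[2])
        assert np.isnan(m["turning_angle"].iloc[3])

    def test_random_walk_turning_is_unbiased(self, rng):
        heading = 0.0
        x, y = [0.0], [0.0]
        for _ in range(4000):
            heading += rng.normal(0, 0.5)
            x.append(x[-1] + np.cos(heading))
            y.append(y[-1] + np.sin(heading))
        tr = compute_step_metrics(self._traj(list(zip(x, y))), fps=25, scale=1.0)
        turns = tr.metrics["turning_angle"].dropna()
        se = turns.std() / np.sqrt(len(turns))
        assert abs(turns.mean()) < 3 * se

    def test_wrap_angle_boundaries(self):
        a = np.array([0, np.pi, -np.pi, 3 * np.pi / 2, -3 * np.pi / 2, 5 * np.pi])
        w = np.asarray(wrap_angle(a))
        assert (w > -np.pi).all() and (w <= np.pi).all()
        np.testing.assert_allclose(np.cos(w), np.cos(a), atol=1e-12)
        np.testing.assert_allclose(np.sin(w), np.sin(a), atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-100.0, max_value=100.0))
    def test_wrap_angle_preserves_direction(self, a):
        w = float(wrap_angle(a))
        assert -np.pi < w <= np.pi
        assert np.cos(w) == pytest.approx(np.cos(a), abs=1e-9)
        assert np.sin(w) == pytest.approx(np.sin(a), abs=1e-9)


class TestBuildTrajectoryTable:
    def test_table_carries_ids_metrics_and_degrees(self):
        rows = [(t, 10.0 + 3 * t, 20.0) for t in range(5)]
        table = det_table(rows)
        trajs = link_particles(table, LinkParams())
        out = build_trajectory_table(table, trajs, fps=25, scale=1.0)
        assert (out["id"] == "v.avi-0").all()
        assert out["step_length"].iloc[1:].tolist() == [3.0] * 4
        np.testing.assert_allclose(
            out["abs_angle_deg"].iloc[1:], np.degrees(out["abs_angle"].iloc[1:])
        )

    def test_empty_input_gives_empty_table(self):
        table = det_table([])
        out = build_trajectory_table(table, {}, fps=25, scale=1.0)
        assert out.empty
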