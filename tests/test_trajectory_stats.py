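import numpy as np
import pandas as pd
import pytest

from vidtrack import filter_data, min_detections_for_rate, summarize_trajectories


def traj_table(rows, video="v.avi", traj_id=0, **extra):
    """rows: (frame, x, y); step metrics computed from positions."""
    frames = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows], float)
    y = np.array([r[2] for r in rows], float)
    step = np.concatenate([[np.nan], np.hypot(np.diff(x), np.diff(y))])
    ang = np.concatenate([[np.nan], np.arctan2(-np.diff(y), np.diff(x))])
    turn = np.full(len(rows), np.nan)
    if len(rows) > 2:
        turn[2:] = np.diff(ang[1:])
    df = pd.DataFrame(
        {
            "video": video,
            "traj_id": traj_id,
            "id": f"{video}-{traj_id}",
            "frame": frames,
            "x": x,
            "y": y,
            "step_length": step,
            "abs_angle": ang,
            "turning_angle": turn,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestSummarize:
    def test_duration_and_rate_closed_form(self):
        rows = [(t, 10.0 + t, 5.0) for t in range(10)]  # spans 10 frames
        s = summarize_trajectories(traj_table(rows), fps=25, scale=1.0)
        assert len(s) == 1
        assert s["duration"].iloc[0] == pytest.approx(9 / 25)  # 0.36 s
        assert s["detection_rate"].iloc[0] == 1.0
        assert s["n_detections"].iloc[0] == 10

    def test_gaps_lower_detection_rate_not_duration(self):
        rows = [(t, 10.0 + t, 5.0) for t in [0, 1, 2, 5, 9]]
        s = summarize_trajectories(traj_table(rows), fps=25, scale=1.0)
        assert s["detection_rate"].iloc[0] == 0.5
        assert s["duration"].iloc[0] == pytest.approx(9 / 25)

    def test_ballistic_net_equals_gross(self):
        rows = [(t, 3.0 * t, 4.0 * t) for t in range(8)]
        s = summarize_trajectories(traj_table(rows), fps=25, scale=1.0)
        assert s["net_displacement"].iloc[0] == pytest.approx(
            s["gross_displacement"].iloc[0]
        )
        assert s["mean_speed"].iloc[0] == pytest.approx(5.0 * 25)

    def test_single_detection_degenerate(self):
        s = summarize_trajectories(traj_table([(4, 7.0, 7.0)]), fps=25, scale=1.0)
        assert s["duration"].iloc[0] == 0.0
        assert s["net_displacement"].iloc[0] == 0.0
        assert np.isnan(s["median_step"].iloc[0])
        assert np.isnan(s["sd_step"].iloc[0])

    def test_net_never_exceeds_gross(self, rng):
        pieces = []
        for tid in range(6):
            pts = np.cumsum(rng.normal(0, 3, (20, 2)), axis=0)
            pieces.append(
                traj_table([(t, p[0], p[1]) for t, p in enumerate(pts)], traj_id=tid)
            )
        s = summarize_trajectories(pd.concat(pieces), fps=25, scale=1.0)
        assert (s["net_displacement"] <= s["gross_displacement"] + 1e-9).all()

    def test_morphology_columns_aggregated(self):
        rows = [(t, 10.0 + t, 5.0) for t in range(5)]
        table = traj_table(rows, area=np.array([10.0, 12, 14, 16, 18]))
        s = summarize_trajectories(table, fps=25, scale=1.0)
        assert s["area_mean"].iloc[0] == pytest.approx(14.0)
        assert s["area_median"].iloc[0] == pytest.approx(14.0)
        assert s["area_sd"].iloc[0] == pytest.approx(np.std([10, 12, 14, 16, 18], ddof=1))
        assert s["area_iqr"].iloc[0] == pytest.approx(4.0)

    def test_empty_input_gives_empty_output(self):
        empty = traj_table([(0, 0.0, 0.0)]).iloc[:0]
        s = summarize_trajectories(empty, fps=25, scale=1.0)
        assert s.empty

    def test_scale_applied_to_displacements(self):
        rows = [(t, 10.0 + 3 * t, 5.0) for t in range(4)]
        s1 = summarize_trajectories(traj_table(rows), fps=25, scale=1.0)
        # step metrics in the table are already in μm; net is computed from
        # pixel positions with the scale argument
        s2 = summarize_trajectories(traj_table(rows), fps=25, scale=2.0)
        assert s2["net_displacement"].iloc[0] == pytest.approx(
            2 * s1["net_displacement"].iloc[0]
        )


def summary_row(**over):
    base = dict(
        id="v-0", video="v", traj_id=0, n_detections=10, first_frame=0,
        last_frame=9, duration=0.36, detection_rate=1.0, net_displacement=100.0,
        gross_displacement=150.0, median_step=5.0, mean_step=5.0, sd_step=1.0,
        mean_speed=125.0, mean_turning=0.0, sd_turning=0.3,
    )
    base.update(over)
    return base


class TestFilterData:
    def test_reference_worked_example(self):
        # 10-frame span at 80%: 8 detections pass, 7 fail
        ok = summary_row(n_detections=8, detection_rate=0.8)
        bad = summary_row(id="v-1", traj_id=1, n_detections=7, detection_rate=0.7)
        out = filter_data(pd.DataFrame([ok, bad]))
        assert list(out["id"]) == ["v-0"]

    def test_boundary_semantics(self):
        rows = pd.DataFrame(
            [
                summary_row(id="net", net_displacement=50.0),       # >= keeps
                summary_row(id="dur", duration=0.2),                # >= keeps
                summary_row(id="step", median_step=2.0),            # strict > drops
                summary_row(id="step2", median_step=2.0001),        # just above keeps
            ]
        )
        out = filter_data(rows)
        assert sorted(out["id"]) == ["dur", "net", "step2"]

    def test_immobile_debris_removed(self):
        rows = pd.DataFrame(
            [summary_row(id="mover"), summary_row(id="debris", net_displacement=0.5)]
        )
        assert list(filter_data(rows)["id"]) == ["mover"]

    def test_relaxing_thresholds_is_monotone(self, rng):
        rows = pd.DataFrame(
            [
                summary_row(
                    id=f"t{i}",
                    net_displacement=rng.uniform(0, 120),
                    duration=rng.uniform(0, 0.5),
                    detection_rate=rng.uniform(0.4, 1.0),
                    median_step=rng.uniform(0, 5),
                )
                for i in range(40)
            ]
        )
        strict = set(filter_data(rows, 50, 0.2, 0.8, 2)["id"])
        for relaxed in (
            filter_data(rows, 25, 0.2, 0.8, 2),
            filter_data(rows, 50, 0.1, 0.8, 2),
            filter_data(rows, 50, 0.2, 0.5, 2),
            filter_data(rows, 50, 0.2, 0.8, 1),
        ):
            assert strict <= set(relaxed["id"])

    def test_all_zero_thresholds_is_identity(self):
        rows = pd.DataFrame(
            [
                summary_row(id="a"),
                summary_row(id="single", median_step=np.nan, net_displacement=0.0,
                            duration=0.0),
            ]
        )
        out = filter_data(rows, 0, 0, 0, -1)
        assert list(out["id"]) == ["a", "single"]

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError, match="min_net"):
            filter_data(pd.DataFrame([summary_row()]), min_net=-5)

    def test_empty_input(self):
        out = filter_data(pd.DataFrame(columns=["net_displacement"]))
        assert out.empty


class TestMinDetectionsForRate:
    @pytest.mark.parametrize(
        "span,rate,expected",
        [(10, 0.8, 8), (5, 0.8, 4), (7, 0.8, 6), (10, 1.0, 10), (3, 0.5, 2)],
    )
    def test_values(self, span, rate, expected):
        assert min_detections_for_rate(span, rate) == expected

    def test_result_satisfies_rate(self):
        for span in range(1, 40):
            k = min_detections_for_rate(span, 0.8)
            assert k / span >= 0.8 > (k - 1) / span
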