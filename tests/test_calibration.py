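"""Calibration pipeline: geometry, scoring, fits, event counting, rates."""

import numpy as np
import pandas as pd
import pytest

from antactivity.calibration import (
    CalibrationError,
    ColonyMeta,
    ColonyNetworkData,
    TrackTable,
    build_proximity_networks,
    calibrate,
    calibrate_tracks,
    colony_summaries,
    count_reverse_contagion_events,
    estimate_delta,
    estimate_gamma0,
    fit_network_scaling,
    read_network_dataset,
    read_track_table,
    reverse_contagion_slope,
    score_activity,
    write_network_dataset,
    write_track_table,
)


def make_tracks(rows, pixel_mm=0.5, dt=0.0667):
    df = pd.DataFrame(rows, columns=["colony", "frame", "ant", "x_mm", "y_mm"])
    meta = {
        str(c): ColonyMeta(colony=str(c), n_nominal=df[df.colony == c]["ant"].nunique(),
                           dt=dt, pixel_mm=pixel_mm)
        for c in df["colony"].unique()
    }
    return TrackTable(df=df, meta=meta)


class TestProximityNetworks:
    def test_contact_radius_is_inclusive_threshold(self):
        rows = [
            ("c", 0, 0, 0.0, 0.0), ("c", 0, 1, 5.9, 0.0),
            ("c", 1, 0, 0.0, 0.0), ("c", 1, 1, 6.1, 0.0),
            ("c", 2, 0, 0.0, 0.0), ("c", 2, 1, 6.0, 0.0),
        ]
        nets = build_proximity_networks(make_tracks(rows), radius=6.0)
        edges = nets["c"].edges
        assert edges[0].tolist() == [[0, 1]]   # 5.9 mm: contact
        assert edges[1].shape == (0, 2)        # 6.1 mm: no contact
        assert edges[2].tolist() == [[0, 1]]   # exactly 6 mm: tie counts

    def test_collinear_ants_form_a_path(self):
        rows = [("c", 0, i, 4.0 * i, 0.0) for i in range(3)]
        nets = build_proximity_networks(make_tracks(rows), radius=6.0)
        assert sorted(map(tuple, nets["c"].edges[0])) == [(0, 1), (1, 2)]

    def test_missing_coordinates_are_skipped(self):
        rows = [
            ("c", 0, 0, 0.0, 0.0), ("c", 0, 1, np.nan, 0.0),
            ("c", 1, 0, 0.0, 0.0), ("c", 1, 1, 1.0, 0.0),
        ]
        nets = build_proximity_networks(make_tracks(rows), radius=6.0)
        assert nets["c"].edges[0].shape == (0, 2)
        assert nets["c"].edges[1].tolist() == [[0, 1]]


class TestScoreActivity:
    def test_stationary_ant_is_never_active(self):
        rows = [("c", f, 0, 1.0, 1.0) for f in range(5)] + [
            ("c", f, 1, 10.0, 10.0 + f) for f in range(5)
        ]
        active, scored = score_activity(make_tracks(rows))["c"]
        assert not active[:, 0].any()
        assert active[1:, 1].all()

    def test_one_pixel_displacement_is_active(self):
        rows = [("c", 0, 0, 0.0, 0.0), ("c", 1, 0, 0.5, 0.0),
                ("c", 0, 1, 3.0, 0.0), ("c", 1, 1, 3.49, 0.0)]
        active, scored = score_activity(make_tracks(rows, pixel_mm=0.5))["c"]
        assert bool(active[1, 0]) is True      # exactly one pixel
        assert bool(active[1, 1]) is False     # just below threshold

    def test_frame_zero_is_unscored(self):
        rows = [("c", f, 0, float(f), 0.0) for f in range(3)]
        active, scored = score_activity(make_tracks(rows))["c"]
        assert not scored[0, 0] and scored[1:, 0].all()

    def test_single_frame_track_is_unusable(self):
        with pytest.raises(CalibrationError, match="activity-scoring"):
            score_activity(make_tracks([("c", 0, 0, 1.0, 1.0)]))


class TestNetworkScalingFit:
    def test_exact_power_law_recovery(self):
        sizes = np.linspace(40, 360, 16)
        fit = fit_network_scaling(sizes, 0.0944 * sizes ** 1.47)
        assert fit.E0 == pytest.approx(0.0944, rel=1e-10)
        assert fit.alpha == pytest.approx(1.47, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.in_range

    def test_constant_edges_flagged_out_of_range(self):
        fit = fit_network_scaling([40, 100, 300], [7.0, 7.0, 7.0])
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)
        assert not fit.in_range

    def test_zero_edge_colonies_are_excluded(self):
        sizes = np.array([40.0, 80.0, 160.0, 320.0])
        E = 0.1 * sizes ** 1.5
        E[0] = 0.0
        fit = fit_network_scaling(sizes, E)
        assert fit.alpha == pytest.approx(1.5, abs=1e-10)

    def test_too_few_colonies(self):
        with pytest.raises(CalibrationError, match="network-scaling"):
            fit_network_scaling([40, 80], [1.0, 2.0])


class TestReverseContagionSlope:
    def test_exact_proportionality(self):
        # Construct A so that y = 2 A^2 E / N^2 equals 0.519 N exactly.
        N = np.array([50.0, 100.0, 200.0, 400.0])
        E = N.copy()
        A = np.sqrt(0.519 * N ** 3 / (2 * E))
        assert reverse_contagion_slope(N, E, A, "origin") == pytest.approx(0.519, rel=1e-12)

    def test_no_activity_is_degenerate_zero(self):
        q = reverse_contagion_slope([50, 100, 200], [5, 10, 20], [0, 0, 0])
        assert q == 0.0

    def test_finite_size_regressor_removes_leading_bias(self):
        # y generated from the exact steady-state identity with x -> 0.
        N = np.array([100.0, 200.0, 400.0, 800.0])
        A = 1.5 * N ** 0.765
        q_true = 0.52
        y = q_true * (N - A)
        E = y * N ** 2 / (2 * A ** 2)
        assert reverse_contagion_slope(N, E, A, "finite_size") == pytest.approx(q_true, rel=1e-12)
        assert reverse_contagion_slope(N, E, A, "origin") < q_true

    def test_unknown_regressor(self):
        with pytest.raises(CalibrationError):
            reverse_contagion_slope([1, 2, 3], [1, 2, 3], [1, 1, 1], "magic")


class TestRateEstimates:
    def test_reported_counts_worked_example(self):
        probability, gamma0 = estimate_gamma0(9861, 800, 0.0667)
        assert probability == pytest.approx(0.0811, abs=5e-5)
        assert gamma0 == pytest.approx(1.2163, abs=5e-4)
        assert estimate_delta(0.519, gamma0) == pytest.approx(0.6313, abs=5e-4)

    def test_no_events_gives_zero(self):
        assert estimate_gamma0(1000, 0, 0.0667) == (0.0, 0.0)

    def test_domain_errors(self):
        with pytest.raises(CalibrationError):
            estimate_gamma0(0, 0, 0.0667)
        with pytest.raises(CalibrationError):
            estimate_gamma0(10, 20, 0.0667)
        with pytest.raises(CalibrationError):
            estimate_delta(0.0, 1.0)


def hand_built_colony():
    """3 ants, 3 frames with known interactions and deactivations.

    Frame 0: edges (0,1), (1,2); ants 0,1 active, 2 inactive.
    Frame 1: ant 1 no longer active; edge (0,1); ant 0 active.
    Frame 2: all inactive.
    """
    edges = [np.array([[0, 1], [1, 2]]), np.array([[0, 1]]),
             np.empty((0, 2), dtype=int)]
    active = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=bool)
    scored = np.ones_like(active)
    return ColonyNetworkData(colony="h", n=3, edges=edges, active=active, scored=scored)


class TestEventCounting:
    def test_hand_enumerated_dialects(self):
        data = hand_built_colony()
        # Frame 0 -> 1: one active-active edge (0,1); ant 1 deactivates.
        # Frame 1 -> 2: no active-active edge (ant 1 inactive at frame 1).
        assert count_reverse_contagion_events(data, unit="interaction") == (2, 1)
        assert count_reverse_contagion_events(data, unit="edge") == (1, 1)
        assert count_reverse_contagion_events(data, unit="ant") == (2, 1)

    def test_unknown_unit(self):
        with pytest.raises(CalibrationError):
            count_reverse_contagion_events(hand_built_colony(), unit="bogus")


class TestCalibrate:
    def test_requires_three_colonies(self):
        with pytest.raises(CalibrationError, match="network-scaling"):
            calibrate({"a": hand_built_colony()})

    def test_degenerate_no_activity_is_flagged(self):
        dataset = {}
        rng = np.random.default_rng(0)
        for i, n in enumerate((10, 20, 40)):
            T = 4
            edges = [
                np.array([[0, 1], [1, 2]]) for _ in range(T)
            ]
            active = np.zeros((T, n), dtype=bool)
            dataset[f"c{i}"] = ColonyNetworkData(
                colony=f"c{i}", n=n, edges=edges, active=active,
                scored=np.ones_like(active),
            )
        result = calibrate(dataset, dt=0.0667)
        assert "q degenerate (no active ants)" in result.flags
        assert any("gamma0 degenerate" in f for f in result.flags)
        assert result.E0 > 0  # structural fit still available

    def test_scale_invariance_of_track_pipeline(self):
        from antactivity.synthetic import FixtureSpec, generate_track_fixture

        spec = FixtureSpec(colony_sizes=(40, 60, 90), n_frames=40, burn_in=10, seed=3)
        tracks, _ = generate_track_fixture(spec)
        res1 = calibrate_tracks(tracks, radius=6.0, pixel_mm=0.5)
        factor = 3.7
        scaled = TrackTable(
            df=tracks.df.assign(
                x_mm=tracks.df.x_mm * factor, y_mm=tracks.df.y_mm * factor
            ),
            meta=tracks.meta,
        )
        res2 = calibrate_tracks(scaled, radius=6.0 * factor, pixel_mm=0.5 * factor)
        assert res2.E0 == pytest.approx(res1.E0, rel=1e-12)
        assert res2.alpha == pytest.approx(res1.alpha, rel=1e-12)
        assert res2.q == pytest.approx(res1.q, rel=1e-12)
        assert res2.gamma0 == pytest.approx(res1.gamma0, rel=1e-12)

    def test_result_never_reports_beta0(self):
        # The activation rate is structurally unidentifiable from video-like
        # data (inactive and refractory are indistinguishable), so the result
        # type deliberately has no such field.
        from antactivity.calibration import CalibrationResult
        import dataclasses

        names = {f.name for f in dataclasses.fields(CalibrationResult)}
        assert "beta0" not in names


class TestRoundTrips:
    def test_network_dataset_roundtrip(self, tmp_path):
        data = {"h": hand_built_colony()}
        write_network_dataset(data, tmp_path)
        back = read_network_dataset(tmp_path)
        assert back.keys() == data.keys()
        for f in range(3):
            assert np.array_equal(back["h"].edges[f], data["h"].edges[f])
        assert np.array_equal(back["h"].active, data["h"].active)
        assert np.array_equal(back["h"].scored, data["h"].scored)

    def test_track_table_roundtrip(self, tmp_path):
        rows = [("c", f, a, float(f + a), float(a)) for f in range(3) for a in range(2)]
        tracks = make_tracks(rows)
        write_track_table(tracks, tmp_path)
        back = read_track_table(tmp_path)
        assert back.meta["c"] == tracks.meta["c"]
        pd.testing.assert_frame_equal(
            back.df.astype({"colony": str}), tracks.df.astype({"colony": str})
        )
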