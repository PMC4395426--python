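"""Arrival detection, lead tracking, switch counting, rotation angles,
replicate statistics and the border-count experiment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imcsim.analysis import (
    AnalysisError,
    MigrationSummary,
    border_count_experiment,
    count_lead_switches,
    detect_arrival,
    max_rotation_angle,
    polar_separation,
    relative_lead,
    replicate_seed,
    replicate_stats,
    summarize_migration,
)
from imcsim.integrator import Trajectory


def synthetic_trajectory(
    polar_axial=None,
    border_x=None,
    times=None,
    oocyte_x=20.0,
    polar_ids=(10, 11),
    dim=3,
):
    """Hand-built trajectory: one border cell moving along x, two polar
    cells at given axial positions, one oocyte-surface cell."""
    times = np.asarray(times if times is not None else [0.0, 1.0, 2.0, 3.0], float)
    T = len(times)
    border_x = np.asarray(
        border_x if border_x is not None else np.full(T, 5.0), float
    )
    polar_axial = np.asarray(
        polar_axial
        if polar_axial is not None
        else np.stack([np.full(T, 5.0), np.full(T, 5.2)], axis=1),
        float,
    )
    frames = np.zeros((T, 4, dim))
    frames[:, 0, 0] = border_x
    frames[:, 1, 0] = polar_axial[:, 0]
    frames[:, 1, 1] = 0.5
    frames[:, 2, 0] = polar_axial[:, 1]
    frames[:, 2, 1] = -0.5
    frames[:, 3, 0] = oocyte_x
    return Trajectory(
        times=times,
        frames=frames,
        ids=np.array([0, polar_ids[0], polar_ids[1], 99]),
        cell_types=np.array(["border", "polar", "polar", "oocyte_surface"]),
        group_ids=np.array([0, 0, 0, 2]),
        migratory=np.array([True, False, False, False]),
        fixed=np.array([False, False, False, True]),
    )


class TestDetectArrival:
    def test_first_contact_time(self):
        """The border cell first comes within one diameter of the oocyte
        at t = 2."""
        traj = synthetic_trajectory(border_x=[5.0, 15.0, 19.5, 19.8])
        assert detect_arrival(traj) == 2.0

    def test_never_approaches(self):
        traj = synthetic_trajectory(border_x=[5.0, 6.0, 7.0, 8.0])
        assert detect_arrival(traj) is None

    def test_starts_in_contact(self):
        traj = synthetic_trajectory(border_x=[19.5, 19.5, 19.5, 19.5])
        assert detect_arrival(traj) == 0.0

    def test_truncation_before_arrival_censors(self):
        traj = synthetic_trajectory(border_x=[5.0, 15.0, 19.5, 19.8])
        assert detect_arrival(traj.truncated(1.0)) is None

    def test_requires_oocyte_layer(self):
        traj = synthetic_trajectory()
        keep = traj.cell_types != "oocyte_surface"
        bare = Trajectory(
            times=traj.times,
            frames=traj.frames[:, keep, :],
            ids=traj.ids[keep],
            cell_types=traj.cell_types[keep],
            group_ids=traj.group_ids[keep],
            migratory=traj.migratory[keep],
            fixed=traj.fixed[keep],
        )
        with pytest.raises(AnalysisError, match="oocyte"):
            detect_arrival(bare)


class TestRelativeLead:
    def test_lead_in_micrometres(self):
        """Axial positions 10.2 and 10.0 diameters give a 1.4 um lead."""
        T = 4
        traj = synthetic_trajectory(
            polar_axial=np.tile([10.2, 10.0], (T, 1))
        )
        _, lead = relative_lead(traj)
        assert np.allclose(lead, 1.4)

    def test_identical_positions_give_zero(self):
        traj = synthetic_trajectory()
        traj2 = synthetic_trajectory(polar_axial=np.tile([5.0, 5.0], (4, 1)))
        _, lead = relative_lead(traj2)
        assert np.allclose(lead, 0.0)

    def test_swapping_ids_negates_series(self):
        a = synthetic_trajectory(
            polar_axial=np.tile([10.2, 10.0], (4, 1)), polar_ids=(10, 11)
        )
        b = synthetic_trajectory(
            polar_axial=np.tile([10.2, 10.0], (4, 1)), polar_ids=(11, 10)
        )
        _, la = relative_lead(a)
        _, lb = relative_lead(b)
        assert np.allclose(la, -lb)

    def test_wrong_polar_count_rejected(self):
        traj = synthetic_trajectory()
        types = traj.cell_types.copy()
        types[2] = "nurse"
        bad = Trajectory(
            times=traj.times,
            frames=traj.frames,
            ids=traj.ids,
            cell_types=types,
            group_ids=traj.group_ids,
            migratory=traj.migratory,
            fixed=traj.fixed,
        )
        with pytest.raises(AnalysisError, match="polar"):
            relative_lead(bad)


class TestCountLeadSwitches:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([0.2, -0.2, 0.15], 2),
            ([0.05, -0.05, 0.05], 0),
            ([0.3, 0.3, 0.3], 0),
            ([0.2, -0.05, 0.2], 0),  # unconfirmed dip does not count
            ([0.2, -0.05, -0.2, 0.05, 0.3], 2),
            ([], 0),
        ],
    )
    def test_hand_counted_examples(self, series, expected):
        if len(series) == 0:
            with pytest.warns(UserWarning):
                assert count_lead_switches(series, 0.1) == expected
        else:
            assert count_lead_switches(series, 0.1) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(-1.0, 1.0, allow_nan=False), min_size=1, max_size=40),
        st.floats(0.01, 0.5),
    )
    def test_invariant_under_sign_flip(self, series, threshold):
        arr = np.array(series)
        assert count_lead_switches(arr, threshold) == count_lead_switches(
            -arr, threshold
        )

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            count_lead_switches([0.2, -0.2], 0.0)


class TestMaxRotation:
    def test_symmetric_leads_near_45_degrees(self):
        """Maximal leads of +-1.4 um at a 3.6 um mean separation give
        2*arcsin(1.4/3.6) ~ 45.8 degrees."""
        lead = np.array([0.0, 1.4, -1.4, 0.0])
        sep = np.full(4, 3.6)
        expected = 2.0 * np.degrees(np.arcsin(1.4 / 3.6))
        assert max_rotation_angle(lead, sep) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(45.8, abs=0.1)

    def test_constant_zero_lead(self):
        assert max_rotation_angle(np.zeros(5), np.full(5, 3.6)) == 0.0

    def test_no_sign_change_returns_zero(self):
        assert max_rotation_angle(np.array([0.5, 1.0, 2.0]), np.full(3, 3.6)) == 0.0

    def test_full_flip_is_180(self):
        lead = np.array([3.6, -3.6])
        assert max_rotation_angle(lead, np.full(2, 3.6)) == pytest.approx(180.0)

    def test_clips_excess_lead_with_warning(self):
        lead = np.array([5.0, -5.0])
        with pytest.warns(UserWarning, match="clipping"):
            angle = max_rotation_angle(lead, np.full(2, 3.6))
        assert angle == pytest.approx(180.0)

    def test_monotone_in_each_lead(self):
        sep = np.full(3, 4.0)
        base = max_rotation_angle(np.array([1.0, -1.0, 0.0]), sep)
        more = max_rotation_angle(np.array([2.0, -1.0, 0.0]), sep)
        assert more > base

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            max_rotation_angle(np.array([]), np.array([]))


def _summary(switches, rotation, arrival):
    return MigrationSummary(
        arrival_time_h=arrival,
        lead_times_h=np.arange(3.0),
        lead_um=np.zeros(3),
        switch_count=switches,
        max_rotation_deg=rotation,
        polar_axial_um=np.zeros((3, 2)),
        mean_polar_separation_um=3.6,
    )


class TestReplicateStats:
    def test_two_runs(self):
        df = replicate_stats([_summary(3, 30.0, 5.0), _summary(4, 40.0, 6.0)])
        assert df.loc["switch_count", "mean"] == 3.5
        assert (df.loc["switch_count", "min"], df.loc["switch_count", "max"]) == (3, 4)

    def test_identical_runs_have_zero_sd(self):
        df = replicate_stats([_summary(2, 20.0, 4.0)] * 3)
        assert df.loc["switch_count", "sd"] == 0.0
        assert df.loc["max_rotation_deg", "sd"] == 0.0

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        switches = rng.integers(0, 8, size=10)
        rotations = rng.uniform(10, 60, size=10)
        arrivals = rng.uniform(3, 7, size=10)
        runs = [
            _summary(int(s), float(r), float(a))
            for s, r, a in zip(switches, rotations, arrivals)
        ]
        df = replicate_stats(runs)
        assert df.loc["switch_count", "mean"] == pytest.approx(switches.mean())
        assert df.loc["max_rotation_deg", "sd"] == pytest.approx(
            rotations.std(ddof=1)
        )
        assert df.loc["arrival_time_h", "min"] == pytest.approx(arrivals.min())

    def test_censored_runs_counted(self):
        df = replicate_stats([_summary(1, 10.0, 5.0), _summary(1, 10.0, None)])
        assert df.attrs["n_censored"] == 1
        assert df.loc["arrival_time_h", "n"] == 1

    def test_single_run_rejected(self):
        with pytest.raises(AnalysisError):
            replicate_stats([_summary(1, 10.0, 5.0)])


class TestBorderCountExperiment:
    def test_single_count_self_normalises(self):
        def runner(n_border, seed):
            return synthetic_trajectory(border_x=[5.0, 15.0, 19.5, 19.8])

        df = border_count_experiment([8], 2, runner, master_seed=1)
        assert df.loc[8, "relative_time"] == 1.0

    def test_relative_times_against_largest(self):
        arrival_step = {4: 3, 6: 2, 8: 1}

        def runner(n_border, seed):
            x = np.full(4, 5.0)
            x[arrival_step[n_border]:] = 19.5
            return synthetic_trajectory(border_x=x)

        df = border_count_experiment([4, 6, 8], 1, runner, master_seed=1)
        assert df.loc[8, "mean_arrival_h"] == 1.0
        assert df.loc[4, "relative_time"] == 3.0
        assert df["mean_arrival_h"].is_monotonic_decreasing

    def test_censored_runs_reported_not_dropped(self):
        def runner(n_border, seed):
            return synthetic_trajectory(border_x=[5.0, 6.0, 7.0, 8.0])

        df = border_count_experiment([6], 2, runner)
        assert df.loc[6, "n_censored"] == 2
        assert np.isnan(df.loc[6, "mean_arrival_h"])

    def test_replicate_seeds_deterministic_and_distinct(self):
        s1 = replicate_seed(5, 6, 0)
        assert s1 == replicate_seed(5, 6, 0)
        assert s1 != replicate_seed(5, 6, 1)
        assert s1 != replicate_seed(5, 8, 0)
        assert 0 <= s1 < 2**31

    def test_empty_counts_rejected(self):
        with pytest.raises(AnalysisError):
            border_count_experiment([], 1, lambda n, s: None)


class TestSummarize:
    def test_summary_consistency(self):
        traj = synthetic_trajectory(
            border_x=[5.0, 15.0, 19.5, 19.8],
            polar_axial=np.array([[5.0, 5.2], [5.3, 5.0], [5.0, 5.25], [5.1, 5.1]]),
        )
        s = summarize_migration(traj)
        assert s.arrival_time_h == 2.0
        _, lead = relative_lead(traj)
        assert np.allclose(s.lead_um, lead)
        assert s.switch_count == count_lead_switches(lead, 0.7)
        assert s.max_rotation_deg == max_rotation_angle(
            lead, polar_separation(traj)
        )
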