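import numpy as np
import pytest

import beadcycle as bc
from beadcycle import synthetic
from beadcycle.models import InvalidParameterError
from beadcycle.segmentation import (
    SegmentationThresholds,
    classify_states,
    compute_features,
    extract_pilus_cycles,
    summarize_events,
)


def simulate(cfg, items, seed, noise_scale=1.0):
    sched = bc.BehaviorSchedule.from_durations(items)
    return synthetic.simulate_trapped_bead(cfg, sched,
                                           rng=np.random.default_rng(seed),
                                           noise_scale=noise_scale)


def segment(traj, cfg, **kw):
    thr = SegmentationThresholds.from_trap(cfg.trap)
    feats = compute_features(traj, cfg.trap.center)
    return classify_states(feats, thr, **kw), thr


def frame_accuracy(traj, truth, found, merge_long_axis=False):
    a = truth.frame_labels(traj.times)
    b = found.frame_labels(traj.times)
    if merge_long_axis:
        a = np.where(a == "long_axis_rotation", "gyration", a)
        b = np.where(b == "long_axis_rotation", "gyration", b)
    return float(np.mean(a == b))


class TestComputeFeatures:
    def test_noiseless_orbit_features(self, trapped_config):
        traj, _ = simulate(trapped_config, [("gyration", 10.0)], 0,
                           noise_scale=0.0)
        feats = compute_features(traj, trapped_config.trap.center)
        orbit = synthetic.gyration_orbit(trapped_config)
        mid = slice(3, -3)
        np.testing.assert_allclose(feats.mean_abs_omega[mid], orbit["omega"],
                                   rtol=0.05)
        # over more than a full turn the path loops: low directedness
        assert feats.directedness[mid].max() < 0.5

    def test_linear_ramp_directed(self):
        t = np.arange(100) / 50.0
        pos = np.column_stack([0.2 * t, np.zeros_like(t)])
        traj = bc.Trajectory(t, pos, 50.0)
        feats = compute_features(traj, np.zeros(2))
        assert feats.directedness[2:-2].min() > 0.95
        np.testing.assert_allclose(feats.radial_velocity[2:-2], 0.2,
                                   rtol=0.05)

    def test_brownian_isotropy(self, weak_trap_config):
        """Mean net angular displacement ~ 0 within 3 SE across windows."""
        cfg = bc.SimulationConfig(trap=weak_trap_config.trap,
                                  bead=weak_trap_config.bead,
                                  frame_rate=50.0, seed=0)
        traj, _ = simulate(cfg, [("brownian", 100.0)], 7)
        feats = compute_features(traj, cfg.trap.center)
        se = feats.net_angle.std(ddof=1) / np.sqrt(len(feats))
        assert abs(feats.net_angle.mean()) < 3 * se

    def test_short_track_rejected(self, trapped_config):
        traj = bc.Trajectory(np.arange(5) / 50.0, np.zeros((5, 2)), 50.0)
        with pytest.raises(InvalidParameterError):
            compute_features(traj, trapped_config.trap.center)


class TestClassifyStates:
    def test_noiseless_gyration_single_interval(self, trapped_config):
        traj, _ = simulate(trapped_config, [("gyration", 20.0)], 0,
                           noise_scale=0.0)
        events, _ = segment(traj, trapped_config, split_long_axis=False)
        assert len(events) == 1
        assert events.events[0].state == "gyration"

    def test_pure_brownian_single_interval(self, trapped_config):
        traj, _ = simulate(trapped_config, [("brownian", 20.0)], 1)
        events, _ = segment(traj, trapped_config)
        assert len(events) == 1
        assert events.events[0].state == "brownian"

    def test_mixed_schedule_accuracy(self, trapped_config):
        """>= 90% frame accuracy on the planted mixed timeline."""
        traj, truth = simulate(trapped_config,
                               [("gyration", 30.0), ("pilus_cycle", 13.0),
                                ("gyration", 10.0), ("brownian", 20.0)], 2)
        events, _ = segment(traj, trapped_config, split_long_axis=False)
        assert frame_accuracy(traj, truth, events) >= 0.90

    def test_unreachable_thresholds_rejected(self):
        with pytest.raises(InvalidParameterError):
            SegmentationThresholds(r_thresh=0.0)

    def test_threshold_monotonicity(self, trapped_config):
        """Raising r_thresh never increases pilus-classified time."""
        traj, _ = simulate(trapped_config,
                           [("gyration", 10.0), ("pilus_cycle", 13.0),
                            ("gyration", 10.0)], 3)
        feats = compute_features(traj, trapped_config.trap.center)
        times = []
        for r_mult in (1.0, 2.0, 4.0):
            thr = SegmentationThresholds.from_trap(trapped_config.trap)
            thr.r_thresh *= r_mult
            ev = classify_states(feats, thr)
            times.append(ev.state_time("pilus_cycle"))
        assert times[0] >= times[1] >= times[2]

    def test_state_fractions_partition(self, trapped_config):
        traj, _ = simulate(trapped_config,
                           [("gyration", 15.0), ("pilus_cycle", 10.0),
                            ("brownian", 10.0)], 4)
        events, _ = segment(traj, trapped_config)
        stats = summarize_events(events)
        assert sum(stats["state_fractions"].values()) == pytest.approx(1.0)


class TestExtractPilusCycles:
    def test_planted_cycle_subphases(self, trapped_config):
        """Recovered sub-phase boundaries within one window of the truth."""
        traj, truth = simulate(trapped_config,
                               [("gyration", 8.0), ("pilus_cycle", 12.0),
                                ("gyration", 8.0)], 5)
        events, thr = segment(traj, trapped_config)
        cycles = extract_pilus_cycles(events, traj,
                                      trapped_config.trap.center, thr)
        assert len(cycles) == 1
        cyc = cycles[0]
        planted = truth.select("pilus_cycle")[0].attrs
        assert cyc.attach == pytest.approx(planted["attach_s"], abs=0.5)
        assert cyc.retract_end == pytest.approx(planted["retract_end_s"],
                                                abs=0.5)
        assert cyc.release_end == pytest.approx(planted["release_end_s"],
                                                abs=0.5)
        assert cyc.duration == pytest.approx(planted["cycle_duration_s"],
                                             abs=0.75)
        assert cyc.release_speed > cyc.retract_speed

    def test_censored_cycle_flagged_incomplete(self, trapped_config):
        """Outward motion with no release before the track ends."""
        cfg = trapped_config
        cfg.pilus.hold_displacement = 2.0
        cfg.pilus.retract_speed = 0.15
        traj, _ = simulate(cfg, [("gyration", 6.0), ("pilus_cycle", 30.0)], 6)
        # truncate mid-retraction: keep gyration plus part of the ramp
        n = int(12.0 * cfg.frame_rate)
        short = bc.Trajectory(traj.times[:n], traj.positions[:n],
                              cfg.frame_rate)
        events, thr = segment(short, cfg)
        cycles = extract_pilus_cycles(events, short, cfg.trap.center, thr)
        assert cycles and not cycles[-1].complete

    def test_mean_duration_recovery(self, trapped_config, dists):
        """Planted cycle-duration sample mean recovered within 10%."""
        planted, recovered = [], []
        for seed in range(4):
            rng = bc.child_rng(100, seed)
            sched = synthetic.pilus_interleaved_schedule(
                rng, 6, dists["pilus_cycle"], dists["pilus_intercycle"])
            traj, truth = synthetic.simulate_trapped_bead(
                trapped_config, sched, rng=rng)
            planted += [e.attrs["cycle_duration_s"]
                        for e in truth.select("pilus_cycle")]
            events, thr = segment(traj, trapped_config)
            cycles = extract_pilus_cycles(events, traj,
                                          trapped_config.trap.center, thr)
            recovered += [c.duration for c in cycles if c.complete]
        assert np.mean(recovered) == pytest.approx(np.mean(planted), rel=0.10)


class TestSummarizeEvents:
    def test_time_partition_arithmetic(self):
        """Pili 100.6 s vs flagellum 230.9 s gives a ~30% pili share."""
        events = bc.EventTable([
            bc.Event("gyration", 0.0, 230.9),
            bc.Event("pilus_cycle", 230.9, 331.5),
        ])
        stats = summarize_events(events)
        assert stats["time_fraction_pili"] == pytest.approx(100.6 / 331.5,
                                                            rel=1e-6)
        assert stats["time_fraction_pili"] == pytest.approx(0.30, abs=0.01)
        assert stats["time_fraction_flagellum"] == pytest.approx(0.70,
                                                                 abs=0.01)

    def test_single_cycle_and_gap(self):
        from beadcycle.segmentation import PilusCycle

        cycles = [
            PilusCycle(0.0, 2.0, 5.0, 6.0, 0.1, 5.0, 0.0),
            PilusCycle(10.0, 12.0, 15.0, 16.0, 0.1, 5.0, 0.0),
        ]
        events = bc.EventTable([bc.Event("pilus_cycle", 0, 6),
                                bc.Event("gyration", 6, 10),
                                bc.Event("pilus_cycle", 10, 16)])
        stats = summarize_events(events, cycles)
        assert stats["pilus_cycle_duration_s"].mean == pytest.approx(6.0)
        assert stats["pilus_cycle_duration_s"].sd == pytest.approx(0.0)
        assert stats["pilus_intercycle_s"].mean == pytest.approx(4.0)

    def test_flagellum_disabled_zero_flagellar_time(self, trapped_config,
                                                    dists):
        """Hook-deletion mimic: no gyration-classified time at default
        thresholds."""
        for seed in range(5):
            rng = bc.child_rng(200, seed)
            sched = synthetic.pilus_interleaved_schedule(
                rng, 2, dists["pilus_cycle_no_flagellum"],
                dists["pilus_intercycle_no_flagellum"], flagellum=False)
            traj, _ = synthetic.simulate_trapped_bead(trapped_config, sched,
                                                      rng=rng)
            events, _ = segment(traj, trapped_config)
            assert events.state_time("gyration", "long_axis_rotation") == 0.0
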