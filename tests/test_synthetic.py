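import math

import numpy as np
import pytest

import beadcycle as bc
from beadcycle import synthetic
from beadcycle.models import InvalidParameterError
from beadcycle.synthetic import AliasingError, FieldOfViewError

from conftest import brownian_traj


class TestThermalReference:
    def test_closed_form_values(self):
        ref = synthetic.thermal_reference(
            bc.TrapModel(0.05, 0.05, temperature=303.15), bc.BeadGeometry(1.5))
        assert ref["variance"][0] == pytest.approx(4.186e-3 / 0.05, rel=1e-3)
        assert ref["corner_frequency"][0] == pytest.approx(0.2815, rel=1e-3)
        assert ref["diffusion"] == pytest.approx(0.148, rel=1e-2)

    def test_stiff_trap_limit(self):
        ref = synthetic.thermal_reference(
            bc.TrapModel(1e6, 1e6), bc.BeadGeometry(1.5))
        assert ref["variance"][0] == pytest.approx(4.19e-9, rel=1e-2)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            bc.TrapModel(-0.05, 0.05)


class TestMatchedTruncnorm:
    @pytest.mark.parametrize("mean,sd,lower", [
        (12.8, 6.1, 2.0), (17.7, 6.5, 2.0), (10.5, 5.1, 0.5)])
    def test_moments_match_when_feasible(self, mean, sd, lower):
        dist = synthetic.matched_truncnorm(mean, sd, lower=lower)
        m, v = dist.stats(moments="mv")
        assert float(m) == pytest.approx(mean, rel=1e-6)
        assert float(np.sqrt(v)) == pytest.approx(sd, rel=0.01)

    def test_mean_exact_even_when_sd_infeasible(self):
        # SD 57.3 is not attainable on [40, 180]; the mean must still match
        dist = synthetic.matched_truncnorm(99.8, 57.3, lower=40.0, upper=180.0)
        m, _ = dist.stats(moments="mv")
        assert float(m) == pytest.approx(99.8, rel=1e-6)

    def test_draws_respect_bounds(self):
        dist = synthetic.matched_truncnorm(12.9, 11.4, lower=2.0)
        draws = dist.rvs(size=2000, random_state=np.random.default_rng(0))
        assert draws.min() >= 2.0


class TestTrappedBeadBrownian:
    def test_ou_stationary_variance_and_autocorrelation(self, weak_trap_config):
        """Per-axis variance -> k_B T/kappa and ACF time -> gamma/kappa."""
        traj = brownian_traj(weak_trap_config, 100_000, seed=1)
        ref = synthetic.thermal_reference(weak_trap_config.trap,
                                          weak_trap_config.bead)
        var = traj.positions.var(axis=0)
        np.testing.assert_allclose(var, ref["variance"], rtol=0.05)
        x = traj.positions[:, 0] - traj.positions[:, 0].mean()
        acf1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        tau_est = -traj.dt / np.log(acf1)
        assert tau_est == pytest.approx(ref["relaxation_time"][0], rel=0.10)

    def test_zero_driving_mean_displacement(self, weak_trap_config):
        """With no driving, the mean sits at the trap centre within 3 SE."""
        traj = brownian_traj(weak_trap_config, 50_000, seed=2)
        ref = synthetic.thermal_reference(weak_trap_config.trap,
                                          weak_trap_config.bead)
        n_eff = len(traj) * traj.dt / (2 * ref["relaxation_time"][0])
        se = np.sqrt(ref["variance"][0] / n_eff)
        assert np.all(np.abs(traj.positions.mean(axis=0)) < 3 * se)

    def test_seed_determinism_bit_identical(self, trapped_config, dists):
        rngs = [bc.child_rng(7, 0) for _ in range(2)]
        scheds = [synthetic.pilus_interleaved_schedule(
            bc.child_rng(7, 1), 2, dists["pilus_cycle"],
            dists["pilus_intercycle"]) for _ in range(2)]
        out = [synthetic.simulate_trapped_bead(trapped_config, s, rng=r)
               for s, r in zip(scheds, rngs)]
        np.testing.assert_array_equal(out[0][0].positions,
                                      out[1][0].positions)
        assert [(e.state, e.start, e.end) for e in out[0][1]] == \
               [(e.state, e.start, e.end) for e in out[1][1]]

    def test_every_frame_covered_by_one_state(self, trapped_config, dists):
        rng = bc.child_rng(3, 0)
        sched = synthetic.pilus_interleaved_schedule(
            rng, 2, dists["pilus_cycle"], dists["pilus_intercycle"])
        traj, events = synthetic.simulate_trapped_bead(trapped_config, sched,
                                                       rng=rng)
        labels = events.frame_labels(traj.times)
        assert all(lab is not None for lab in labels)


class TestGyration:
    def test_noiseless_orbit_radius_and_event(self, trapped_config):
        orbit = synthetic.gyration_orbit(trapped_config)
        sched = bc.BehaviorSchedule.from_durations([("gyration", 10.0)])
        traj, events = synthetic.simulate_trapped_bead(
            trapped_config, sched, rng=np.random.default_rng(0),
            noise_scale=0.0)
        r = np.hypot(*traj.positions[-100:].T)
        assert r.mean() == pytest.approx(orbit["radius"], rel=0.01)
        assert len(events) == 1 and events.events[0].state == "gyration"
        theta = np.unwrap(np.arctan2(traj.positions[:, 1],
                                     traj.positions[:, 0]))
        omega = (theta[-1] - theta[200]) / (traj.times[-1] - traj.times[200])
        assert omega == pytest.approx(orbit["omega"], rel=0.02)

    def test_direction_sign_convention(self, trapped_config):
        """CCW driving gives positive angular velocity; CW negative."""
        for direction, sign in (("CCW", 1.0), ("CW", -1.0)):
            cfg = bc.SimulationConfig(
                trap=trapped_config.trap, bead=trapped_config.bead,
                frame_rate=50.0, seed=0,
                driving=bc.DrivingParams(rot_force=0.3, trans_force=1.2,
                                         gyration_direction=direction))
            sched = bc.BehaviorSchedule.from_durations([("gyration", 5.0)])
            traj, _ = synthetic.simulate_trapped_bead(
                cfg, sched, rng=np.random.default_rng(0), noise_scale=0.0)
            theta = np.unwrap(np.arctan2(traj.positions[:, 1],
                                         traj.positions[:, 0]))
            assert np.sign(theta[-1] - theta[50]) == sign

    def test_gyration_freq_parameterization(self, trapped_config):
        """rot_force derived from a requested orbit frequency reproduces it."""
        cfg = bc.SimulationConfig(
            trap=trapped_config.trap, bead=trapped_config.bead,
            frame_rate=50.0, seed=0,
            driving=bc.DrivingParams(rot_force=None, gyration_freq=2.0,
                                     trans_force=1.2))
        orbit = synthetic.gyration_orbit(cfg)
        assert orbit["frequency"] == pytest.approx(2.0, rel=1e-9)


class TestPilusKinematics:
    def test_noiseless_ramp_hold_release(self, trapped_config):
        """Radial ramp at retract speed, hold, then trap-relaxation decay."""
        cfg = trapped_config
        cfg.pilus.jitter = 0.0
        sched = bc.BehaviorSchedule.from_durations(
            [("pilus_cycle", 12.0, {"anchor_bearing": 0.0})])
        traj, events = synthetic.simulate_trapped_bead(
            cfg, sched, rng=np.random.default_rng(0), noise_scale=0.0)
        attrs = events.events[0].attrs
        r = np.hypot(*traj.positions.T)
        t = traj.times
        # ramp phase: radial speed == retract speed
        ramp = (t > 0.5) & (t < attrs["retract_end_s"] - 0.5)
        slope = np.polyfit(t[ramp], r[ramp], 1)[0]
        assert slope == pytest.approx(cfg.pilus.retract_speed, rel=0.02)
        # hold phase: displacement reached and static
        hold = (t > attrs["retract_end_s"]) & (t < attrs["hold_end_s"])
        assert r[hold].std() < 1e-9
        assert r[hold].mean() == pytest.approx(
            cfg.pilus.hold_displacement, rel=0.02)
        # release: exponential decay with the trap relaxation time
        ref = synthetic.thermal_reference(cfg.trap, cfg.bead)
        rel = (t > attrs["hold_end_s"]) & (r > 0.05)
        if rel.sum() >= 3:
            tau_fit = -1.0 / np.polyfit(t[rel], np.log(r[rel]), 1)[0]
            assert tau_fit == pytest.approx(ref["relaxation_time"][0],
                                            rel=0.25)

    def test_release_retract_speed_ratio(self, trapped_config, dists):
        """Generated release speeds exceed retraction by >= the set factor."""
        rng = bc.child_rng(11, 0)
        sched = synthetic.pilus_interleaved_schedule(
            rng, 3, dists["pilus_cycle"], dists["pilus_intercycle"])
        _, events = synthetic.simulate_trapped_bead(trapped_config, sched,
                                                    rng=rng)
        for ev in events.select("pilus_cycle"):
            ratio = ev.attrs["release_speed_um_s"] / ev.attrs["retract_speed_um_s"]
            assert ratio >= trapped_config.pilus.release_speed_factor

    def test_unphysical_hold_displacement_rejected(self, trapped_config):
        trapped_config.pilus.hold_displacement = 1000.0
        sched = bc.BehaviorSchedule.from_durations([("pilus_cycle", 10.0)])
        with pytest.raises(InvalidParameterError):
            synthetic.simulate_trapped_bead(trapped_config, sched,
                                            rng=np.random.default_rng(0))


class TestFreeSwimmer:
    def test_noiseless_limit_is_a_line(self, defaults):
        cfg = bc.SimulationConfig(
            frame_rate=20.0, seed=0,
            swim=bc.SwimParams(v_push=10.0, v_pull=10.0, tau_push=2.0,
                               tau_pull=1.0, rotational_diffusion=0.0))
        traj, _ = synthetic.simulate_free_swimmer(
            cfg, rng=np.random.default_rng(0), n_sequences=10,
            noise_scale=0.0)
        # all positions lie on one line through the start
        d = traj.positions - traj.positions[0]
        cross = d[:, 0] * d[-1, 1] - d[:, 1] * d[-1, 0]
        assert np.abs(cross).max() < 1e-9

    def test_exponential_duration_means_recovered(self, defaults):
        cfg = bc.SimulationConfig(frame_rate=20.0, seed=0,
                                  swim=bc.SwimParams())
        _, events = synthetic.simulate_free_swimmer(
            cfg, rng=np.random.default_rng(1), n_sequences=1000)
        push = [e.duration for e in events.select("swim_push")]
        pull = [e.duration for e in events.select("swim_pull")]
        assert np.mean(push) == pytest.approx(2.2, rel=0.10)
        assert np.mean(pull) == pytest.approx(1.2, rel=0.10)

    def test_renewal_time_fraction(self):
        cfg = bc.SimulationConfig(frame_rate=20.0, seed=0,
                                  swim=bc.SwimParams())
        _, events = synthetic.simulate_free_swimmer(
            cfg, rng=np.random.default_rng(2), n_sequences=1000)
        t_push = events.state_time("swim_push")
        t_all = t_push + events.state_time("swim_pull")
        assert t_push / t_all == pytest.approx(2.2 / 3.4, abs=0.03)

    def test_negative_tau_rejected(self):
        with pytest.raises(InvalidParameterError):
            bc.SwimParams(tau_push=-1.0)


class TestPoleTrack:
    def test_pure_quadrature_construction(self):
        cfg = bc.SimulationConfig(frame_rate=200.0, seed=0,
                                  pole=bc.PoleParams(noise=0.0))
        sched = bc.BehaviorSchedule.from_durations(
            [("long_axis_rotation", 2.0, {"freq": 25.0, "direction": "CCW"})])
        track, events = synthetic.simulate_pole_track(
            cfg, sched, rng=np.random.default_rng(0), noise_scale=0.0)
        x, y = track.positions.T
        amp = cfg.pole.amplitude
        np.testing.assert_allclose(x ** 2 + y ** 2, amp ** 2, rtol=1e-9)
        assert events.events[0].attrs["freq_hz"] == 25.0

    def test_two_intervals_opposite_directions(self):
        cfg = bc.SimulationConfig(frame_rate=200.0, seed=0)
        sched = synthetic.pole_rotation_schedule(
            np.random.default_rng(0), 20.0, 30.0, n_intervals=2)
        _, events = synthetic.simulate_pole_track(
            cfg, sched, rng=np.random.default_rng(0))
        dirs = [e.attrs["direction"] for e in events]
        assert dirs == ["CCW", "CW"]

    def test_aliasing_rejected(self):
        cfg = bc.SimulationConfig(frame_rate=40.0, seed=0)
        sched = bc.BehaviorSchedule.from_durations(
            [("long_axis_rotation", 1.0, {"freq": 25.0})])
        with pytest.raises(AliasingError):
            synthetic.simulate_pole_track(cfg, sched,
                                          rng=np.random.default_rng(0))

    def test_planted_frequency_sampling_distribution(self, dists):
        """Sample mean of planted CCW frequencies within 2 SE of the target."""
        rng = np.random.default_rng(5)
        draws = dists["freq_ccw"].rvs(size=50, random_state=rng)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 20.4) < 2 * se + 1e-9


class TestRenderImageStack:
    def _traj(self, positions, fr=50.0):
        times = np.arange(len(positions)) / fr
        return bc.Trajectory(times, np.asarray(positions, dtype=float), fr)

    def test_noiseless_argmax_at_spot(self):
        traj = self._traj([[1.0, 1.0], [1.0, 1.0]])
        stack = synthetic.render_image_stack(traj, pixel_size=0.1,
                                             spot_sigma=2.0)
        idx = np.unravel_index(np.argmax(stack.frames[0]), stack.frames[0].shape)
        col = 1.0 / 0.1 - stack.origin_um[0] / 0.1
        row = 1.0 / 0.1 - stack.origin_um[1] / 0.1
        assert idx == (pytest.approx(row, abs=0.5), pytest.approx(col, abs=0.5))

    def test_centroid_identity_subpixel(self):
        """Intensity-weighted centroid of a symmetric spot equals its centre."""
        traj = self._traj([[1.025, 1.075], [1.025, 1.075]])
        stack = synthetic.render_image_stack(traj, pixel_size=0.1,
                                             spot_sigma=2.0, background=0.0)
        img = stack.frames[0].astype(float)
        rows = np.arange(img.shape[0])[:, None]
        cols = np.arange(img.shape[1])[None, :]
        cx = (img * cols).sum() / img.sum() + stack.origin_um[0] / 0.1
        cy = (img * rows).sum() / img.sum() + stack.origin_um[1] / 0.1
        assert cx == pytest.approx(1.025 / 0.1, abs=1e-3)
        assert cy == pytest.approx(1.075 / 0.1, abs=1e-3)

    def test_field_of_view_error_lists_frames(self):
        traj = self._traj([[0.0, 0.0], [50.0, 0.0]])
        with pytest.raises(FieldOfViewError, match="frames"):
            synthetic.render_image_stack(traj, pixel_size=0.1, spot_sigma=2.0,
                                         shape=(64, 64), origin=(-3.0, -3.0))

    def test_tiff_round_trip(self, tmp_path):
        traj = self._traj([[1.0, 1.0], [1.1, 1.0]])
        stack = synthetic.render_image_stack(traj, pixel_size=0.1,
                                             spot_sigma=2.0)
        path = tmp_path / "stack.tif"
        stack.to_tiff(path)
        back = bc.ImageStack.from_tiff(path, 0.1, traj.frame_rate)
        np.testing.assert_array_equal(back.frames, stack.frames)
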