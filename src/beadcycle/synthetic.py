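"""Physics-based synthetic data generator.

Produces seeded, ground-truth-labeled bead trajectories, flagellated-pole
tracks and rendered image stacks with the statistical structure the
downstream inference assumes:

* trapped bead: overdamped Langevin motion in a harmonic trap, driven by
  flagellar gyration (tangential + radial force), kinematic type IV pilus
  attachment cycles (attach -> retract -> hold -> release), long-axis
  rotation (slowed gyration) and pure Brownian motion;
* free swimmer: run-reverse motility with exponential push/pull durations,
  per-sequence speeds and rotational diffusion of the body axis;
* pole track: quadrature rotation signal with per-interval frequency and
  direction, sub-Hz bending, ballistic release.

Driving-free segments use the exact Ornstein--Uhlenbeck discretization
(AR(1) with a = exp(-dt/tau)), which is exact at any step size; the
nonlinear gyration driving is integrated by Euler--Maruyama at a fine step.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import optimize, signal, stats

from .models import (
    KB,
    BeadGeometry,
    BehaviorSchedule,
    Event,
    EventTable,
    ImageStack,
    InvalidParameterError,
    PoleTrack,
    Segment,
    SimulationConfig,
    Trajectory,
    TrapModel,
    assay_defaults,
)

__all__ = [
    "AliasingError",
    "FieldOfViewError",
    "thermal_reference",
    "matched_truncnorm",
    "assay_distributions",
    "simulate_trapped_bead",
    "simulate_free_swimmer",
    "simulate_pole_track",
    "render_image_stack",
    "pilus_interleaved_schedule",
    "activity_schedule",
    "pole_rotation_schedule",
]


class AliasingError(InvalidParameterError):
    """Requested oscillation frequency too close to the Nyquist limit."""


class FieldOfViewError(ValueError):
    """Trajectory leaves the rendered field of view."""


# ---------------------------------------------------------------------------
# Closed-form thermal reference (oracle for the calibration stage)
# ---------------------------------------------------------------------------


def thermal_reference(trap: TrapModel, bead: BeadGeometry) -> dict:
    """Closed-form statistics of a trapped Brownian bead.

    Returns per-axis stationary variance k_B*T/kappa (µm²), relaxation time
    gamma/kappa (s), corner frequency kappa/(2*pi*gamma) (Hz) and the free
    diffusivity k_B*T/gamma (µm²/s).
    """
    gamma = bead.drag
    kt = trap.kt
    kappa = trap.kappa
    return {
        "variance": kt / kappa,
        "relaxation_time": gamma / kappa,
        "corner_frequency": kappa / (2.0 * math.pi * gamma),
        "diffusion": kt / gamma,
    }


# ---------------------------------------------------------------------------
# Moment-matched truncated normals
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _matched_truncnorm_params(mean: float, sd: float, lower: float,
                              upper: float) -> tuple[float, float]:
    def trunc_moments(mu: float, s: float) -> tuple[float, float]:
        a, b = (lower - mu) / s, (upper - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return float(m), float(np.sqrt(v))

    def resid(p):
        mu, ls = p
        m, s_ = trunc_moments(mu, math.exp(ls))
        # mean is the quantity downstream comparisons use; weight it heavily
        return [10.0 * (m - mean), s_ - sd]

    sol = optimize.least_squares(resid, x0=[mean, math.log(sd)],
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    mu, s = float(sol.x[0]), float(math.exp(sol.x[1]))

    # polish: with the scale fixed, make the truncated mean exact
    def mean_err(m0: float) -> float:
        return trunc_moments(m0, s)[0] - mean

    lo, hi = mu - 10 * sd - 1.0, mu + 10 * sd + 1.0
    try:
        if mean_err(lo) * mean_err(hi) < 0:
            mu = float(optimize.brentq(mean_err, lo, hi, xtol=1e-10))
    except ValueError:
        pass
    return mu, s


def matched_truncnorm(mean: float, sd: float, lower: float = 0.0,
                      upper: float = np.inf):
    """Truncated normal whose *truncated* moments match the given mean/SD.

    Printed assay statistics describe the observed (bounded) samples, so the
    generator solves for underlying normal parameters such that the truncated
    distribution reproduces the requested mean exactly and the SD as closely as
    the family permits on [lower, upper].
    """
    if sd <= 0:
        raise InvalidParameterError("sd must be positive")
    if not lower < mean < upper:
        raise InvalidParameterError("mean must lie inside the truncation range")
    mu, s = _matched_truncnorm_params(float(mean), float(sd), float(lower),
                                      float(upper))
    a, b = (lower - mu) / s, (upper - mu) / s
    return stats.truncnorm(a, b, loc=mu, scale=s)


def assay_distributions(defaults: dict | None = None) -> dict:
    """Frozen sampling distributions for every default mean ± SD quantity."""
    d = defaults or assay_defaults()

    def tn(spec: dict):
        return matched_truncnorm(spec["mean"], spec["sd"],
                                 spec.get("lower", 0.0),
                                 spec.get("upper", np.inf))

    sw = d["swim"]
    return {
        "v_push": matched_truncnorm(sw["v_push_um_per_s"]["mean"],
                                    sw["v_push_um_per_s"]["sd"],
                                    lower=sw["speed_floor_um_per_s"]),
        "v_pull": matched_truncnorm(sw["v_pull_um_per_s"]["mean"],
                                    sw["v_pull_um_per_s"]["sd"],
                                    lower=sw["speed_floor_um_per_s"]),
        "activity": tn(d["activity_s"]),
        "rotation_stage": tn(d["rotation_stage_s"]),
        "bending": tn(d["bending_s"]),
        "freq_ccw": tn(d["pole_frequency_Hz"]["ccw"]),
        "freq_cw": tn(d["pole_frequency_Hz"]["cw"]),
        "pilus_cycle": tn(d["pilus"]["cycle_s"]),
        "pilus_intercycle": tn(d["pilus"]["intercycle_s"]),
        "pilus_cycle_no_flagellum": tn(d["pilus"]["cycle_no_flagellum_s"]),
        "pilus_intercycle_no_flagellum": tn(d["pilus"]["intercycle_no_flagellum_s"]),
    }


# ---------------------------------------------------------------------------
# Exact OU sampling (driving-free segments)
# ---------------------------------------------------------------------------


def _ou_exact(rng: np.random.Generator, x0: np.ndarray, center: np.ndarray,
              tau: np.ndarray, var_stat: np.ndarray, dt: float,
              n: int, noise_scale: float = 1.0) -> np.ndarray:
    """Sample n steps of a 2-D OU process exactly at spacing dt.

    Returns positions of shape (n, 2) *excluding* x0 (the next n frames).
    """
    out = np.empty((n, 2))
    for ax in range(2):
        a = math.exp(-dt / tau[ax])
        s = math.sqrt(max(var_stat[ax] * (1.0 - a * a), 0.0)) * noise_scale
        noise = s * rng.standard_normal(n)
        # y_k = a*y_{k-1} + noise_k with y_0 = x0 - center
        y = signal.lfilter([1.0], [1.0, -a], noise,
                           zi=np.array([a * (x0[ax] - center[ax])]))[0]
        out[:, ax] = center[ax] + y
    return out


# ---------------------------------------------------------------------------
# Gyration driving (Euler--Maruyama)
# ---------------------------------------------------------------------------


def derived_rot_force(config: SimulationConfig) -> float:
    """Tangential force: explicit, or from the requested gyration frequency.

    At the steady orbit radius r* = trans_force/kappa the drag balance gives
    omega = rot_force/(gamma*r*), hence
    rot_force = 2*pi*f*gamma*trans_force/kappa.
    """
    drv = config.driving
    if drv.rot_force is not None:
        return drv.rot_force
    kappa = float(np.mean(config.trap.kappa))
    return (2.0 * math.pi * drv.gyration_freq * config.bead.drag
            * drv.trans_force / kappa)


def gyration_orbit(config: SimulationConfig) -> dict:
    """Noise-free steady orbit implied by the driving parameters."""
    kappa = float(np.mean(config.trap.kappa))
    rot = derived_rot_force(config)
    r_star = config.driving.trans_force / kappa
    omega = rot / (config.bead.drag * r_star) if r_star > 0 else 0.0
    return {"radius": r_star, "omega": omega,
            "frequency": omega / (2.0 * math.pi)}


def _integrate_gyration(x0, center, kappa, gamma, rot_force, trans_force,
                        direction_sign, h, n_frames, m_sub, noise):
    """EM integration of the driven trap; returns (n_frames, 2) positions.

    The driving force is tangential (magnitude rot_force, sign = CCW positive)
    plus radial (trans_force, outward) w.r.t. the instantaneous radius from
    the trap centre; near the centre the last polar angle is reused so the
    tangent stays defined.
    """
    cx, cy = float(center[0]), float(center[1])
    kx, ky = float(kappa[0]), float(kappa[1])
    x, y = float(x0[0]), float(x0[1])
    inv_g = 1.0 / gamma
    s = float(direction_sign)
    phi = math.atan2(y - cy, x - cx)
    r_eps = 1e-6
    nx = noise[:, 0].tolist()
    ny = noise[:, 1].tolist()
    out = np.empty((n_frames, 2))
    k = 0
    for i in range(n_frames):
        for _ in range(m_sub):
            dxc = x - cx
            dyc = y - cy
            r = math.hypot(dxc, dyc)
            if r > r_eps:
                urx, ury = dxc / r, dyc / r
                phi = math.atan2(dyc, dxc)
            else:
                urx, ury = math.cos(phi), math.sin(phi)
            utx, uty = -s * ury, s * urx
            fx = -kx * dxc + trans_force * urx + rot_force * utx
            fy = -ky * dyc + trans_force * ury + rot_force * uty
            x += fx * inv_g * h + nx[k]
            y += fy * inv_g * h + ny[k]
            k += 1
        out[i, 0] = x
        out[i, 1] = y
    return out


# ---------------------------------------------------------------------------
# Trapped-bead simulator
# ---------------------------------------------------------------------------


def _frames_of(duration: float, frame_rate: float) -> int:
    return max(1, int(round(duration * frame_rate)))


def simulate_trapped_bead(
    config: SimulationConfig,
    schedule: BehaviorSchedule,
    rng: np.random.Generator | None = None,
    noise_scale: float = 1.0,
) -> tuple[Trajectory, EventTable]:
    """Simulate a bead held in the trap while the attached cell acts on it.

    Schedule states: ``gyration``, ``long_axis_rotation``, ``pilus_cycle``,
    ``brownian``.  Segment boundaries are rounded to the frame grid so the
    ground-truth EventTable and the trajectory share one clock.  Returns the
    frame-rate trajectory and the exact ground-truth event table (pilus
    sub-phases recorded in event attributes).

    ``noise_scale`` multiplies the thermal noise amplitude (0 = noiseless
    deterministic limit; 1 = physical).
    """
    for seg in schedule:
        if seg.state not in ("gyration", "pilus_cycle", "long_axis_rotation",
                             "brownian"):
            raise InvalidParameterError(
                f"state {seg.state!r} not valid for the trapped-bead simulator")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    trap, bead = config.trap, config.bead
    fr = config.frame_rate
    dtf = 1.0 / fr
    h = config.step
    m_sub = max(1, int(round(dtf / h)))
    h = dtf / m_sub
    gamma = bead.drag
    kappa = trap.kappa
    ref = thermal_reference(trap, bead)
    tau = ref["relaxation_time"]
    var_stat = ref["variance"]
    if h > float(np.min(tau)) / 10.0:
        import warnings

        warnings.warn("integration step coarser than tau/10; OU statistics "
                      "may be biased", stacklevel=2)
    rot_base = derived_rot_force(config)
    sign = 1.0 if config.driving.gyration_direction == "CCW" else -1.0
    sub_noise_sd = math.sqrt(2.0 * float(np.mean(var_stat) / np.mean(tau)) * h)

    pil = config.pilus
    if pil.retract_speed > 0 and pil.hold_displacement > 0:
        implied = pil.hold_displacement * float(np.mean(kappa))
        if implied > 50.0 * config.driving.trans_force:
            raise InvalidParameterError(
                "hold_displacement implies an unphysical pilus force")

    x = trap.center.copy()
    t0 = 0.0
    frames: list[np.ndarray] = []
    events: list[Event] = []
    for seg in schedule:
        n = _frames_of(seg.duration, fr)
        t1 = t0 + n * dtf
        if seg.state == "brownian":
            pos = _ou_exact(rng, x, trap.center, tau, var_stat, dtf, n,
                            noise_scale)
            events.append(Event("brownian", t0, t1))
        elif seg.state in ("gyration", "long_axis_rotation"):
            rot = seg.params.get("rot_force", rot_base)
            if seg.state == "long_axis_rotation":
                rot *= seg.params.get("slow_factor", config.driving.slow_factor)
            trans = seg.params.get("trans_force", config.driving.trans_force)
            noise = (sub_noise_sd * noise_scale
                     * rng.standard_normal((n * m_sub, 2)))
            pos = _integrate_gyration(x, trap.center, kappa, gamma, rot, trans,
                                      sign, h, n, m_sub, noise)
            events.append(Event(seg.state, t0, t1,
                                {"rot_force": rot, "trans_force": trans}))
        elif seg.state == "pilus_cycle":
            pos, attrs = _pilus_cycle_frames(config, seg, x, rng, n,
                                             noise_scale, tau, var_stat)
            events.append(Event("pilus_cycle", t0, t1, attrs))
        t0 = t1
        x = pos[-1]
        frames.append(pos)
    positions = np.vstack(frames)
    times = np.arange(1, len(positions) + 1) * dtf
    traj = Trajectory(times, positions, fr,
                      aux={"scenario": "trapped", "seed": config.seed})
    return traj, EventTable(events)


def _pilus_cycle_frames(config, seg, x_attach, rng, n, noise_scale, tau,
                        var_stat):
    """Kinematic pilus attachment cycle: retract, hold, fast release.

    The tether prescribes the bead position (small localization-scale jitter)
    while attached; on release the tether is removed and the bead relaxes
    into the trap as an exact OU path, so the release speed ~ r*kappa/gamma
    exceeds the retraction speed by construction.
    """
    pil = config.pilus
    fr = config.frame_rate
    dtf = 1.0 / fr
    total = n * dtf
    speed = seg.params.get("retract_speed", pil.retract_speed)
    d_target = seg.params.get("hold_displacement", pil.hold_displacement)
    jitter = seg.params.get("jitter", pil.jitter) * noise_scale
    # release window: a few trap relaxation times, resolvable on the frame grid
    t_rel = min(0.5, max(8.0 * float(np.max(tau)), 3.0 * dtf))
    t_rel = min(t_rel, 0.2 * total)
    t_retract = d_target / speed if speed > 0 else 0.45 * total
    t_retract = min(t_retract, 0.45 * total)
    d_reached = speed * t_retract if speed > 0 else d_target
    n_rel = max(1, int(round(t_rel * fr)))
    n_ret = max(1, int(round(t_retract * fr)))
    n_ret = min(n_ret, n - n_rel - 1) if n - n_rel - 1 >= 1 else max(n - n_rel - 1, 0)
    n_hold = n - n_ret - n_rel
    if n_hold < 0:
        n_hold, n_ret = 0, n - n_rel

    center = config.trap.center
    rad = x_attach - center
    r0 = float(np.hypot(*rad))
    if "anchor_bearing" in seg.params:
        bearing = float(seg.params["anchor_bearing"])
    else:
        base = math.atan2(rad[1], rad[0]) if r0 > 1e-6 else rng.uniform(
            0.0, 2.0 * math.pi)
        bearing = base + rng.uniform(-math.pi / 3.0, math.pi / 3.0)
    u = np.array([math.cos(bearing), math.sin(bearing)])

    parts = []
    if n_ret:
        tt = (np.arange(1, n_ret + 1) * dtf)[:, None]
        parts.append(x_attach + speed * tt * u)
    hold_point = x_attach + d_reached * u
    if n_hold:
        parts.append(np.tile(hold_point, (n_hold, 1)))
    tether = np.vstack(parts) if parts else np.empty((0, 2))
    if jitter > 0 and len(tether):
        tether = tether + jitter * rng.standard_normal(tether.shape)
    release = _ou_exact(rng, hold_point, center, tau, var_stat, dtf, n_rel,
                        noise_scale)
    pos = np.vstack([tether, release]) if len(tether) else release

    t0 = seg.start
    retract_speed_actual = d_reached / (n_ret * dtf) if n_ret else 0.0
    release_speed = float(np.hypot(*(hold_point - center))) / max(
        float(np.max(tau)), dtf)
    attrs = {
        "attach_s": t0,
        "retract_end_s": t0 + n_ret * dtf,
        "hold_end_s": t0 + (n_ret + n_hold) * dtf,
        "release_end_s": t0 + n * dtf,
        "anchor_bearing_rad": bearing,
        "retract_speed_um_s": retract_speed_actual,
        "release_speed_um_s": release_speed,
        "hold_displacement_um": d_reached,
        "cycle_duration_s": n * dtf,
    }
    return pos, attrs


# ---------------------------------------------------------------------------
# Free swimmer
# ---------------------------------------------------------------------------


def simulate_free_swimmer(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_sequences: int | None = None,
    noise_scale: float = 1.0,
) -> tuple[Trajectory, EventTable]:
    """Quasi-2D run-reverse swimmer: alternating push/pull sequences.

    Durations are exponential with means ``tau_push``/``tau_pull``; speeds
    are drawn per sequence from moment-matched truncated normals when the
    corresponding SD is nonzero, else held constant.  The body axis evolves
    by rotational diffusion and is continuous across reversals (the motion
    direction flips, the cell does not turn); positional Brownian noise is
    added.  The ground-truth axis is stored in ``traj.aux['axis']``.
    """
    sw = config.swim
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fr = config.frame_rate
    dtf = 1.0 / fr
    if n_sequences is None:
        if config.total_time is None:
            raise InvalidParameterError("need total_time or n_sequences")
        n_sequences = max(2, int(math.ceil(
            config.total_time / ((sw.tau_push + sw.tau_pull) / 2.0))))

    dists = {}
    if sw.v_push_sd > 0:
        dists["push"] = matched_truncnorm(sw.v_push, sw.v_push_sd,
                                          lower=sw.speed_floor)
    if sw.v_pull_sd > 0:
        dists["pull"] = matched_truncnorm(sw.v_pull, sw.v_pull_sd,
                                          lower=sw.speed_floor)

    states, durations, speeds = [], [], []
    push = True
    for _ in range(n_sequences):
        tau = sw.tau_push if push else sw.tau_pull
        durations.append(float(rng.exponential(tau)))
        key = "push" if push else "pull"
        if key in dists:
            speeds.append(float(dists[key].rvs(random_state=rng)))
        else:
            speeds.append(sw.v_push if push else sw.v_pull)
        states.append("swim_push" if push else "swim_pull")
        push = not push

    n_frames_seq = [_frames_of(d, fr) for d in durations]
    n_total = sum(n_frames_seq)
    # body axis: rotational diffusion, continuous across reversals
    dtheta = math.sqrt(2.0 * sw.rotational_diffusion * dtf) * noise_scale
    theta = np.cumsum(
        np.concatenate([[rng.uniform(0, 2 * math.pi)],
                        dtheta * rng.standard_normal(n_total - 1)]))
    axis = np.column_stack([np.cos(theta), np.sin(theta)])

    v_signed = np.empty(n_total)
    pos_idx = 0
    events = []
    t = 0.0
    for st, nf, sp in zip(states, n_frames_seq, speeds):
        s = 1.0 if st == "swim_push" else -1.0
        v_signed[pos_idx:pos_idx + nf] = s * sp
        events.append(Event(st, t, t + nf * dtf,
                            {"speed_um_s": sp, "planted_duration_s": nf * dtf}))
        t += nf * dtf
        pos_idx += nf

    d_diff = config.bead.diffusion(config.trap.temperature)
    steps = (v_signed[:, None] * axis * dtf
             + noise_scale * math.sqrt(2.0 * d_diff * dtf)
             * rng.standard_normal((n_total, 2)))
    positions = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    times = np.arange(n_total + 1) * dtf
    axis_full = np.vstack([axis, axis[-1]])
    traj = Trajectory(times, positions, fr,
                      aux={"scenario": "swimmer", "seed": config.seed,
                           "axis": axis_full})
    return traj, EventTable(events)


# ---------------------------------------------------------------------------
# Pole track
# ---------------------------------------------------------------------------


def simulate_pole_track(
    config: SimulationConfig,
    schedule: BehaviorSchedule,
    rng: np.random.Generator | None = None,
    noise_scale: float = 1.0,
) -> tuple[PoleTrack, EventTable]:
    """Flagellated-pole track of a surface-attached predivisional cell.

    States: ``bending`` (sub-Hz large-amplitude oscillation along a fixed
    axis), ``long_axis_rotation`` (quadrature x = A cos, y = +/- A sin;
    + = CCW) and ``released`` (ballistic drift).  Gaussian localization
    noise is added everywhere.
    """
    for seg in schedule:
        if seg.state not in ("bending", "long_axis_rotation", "released"):
            raise InvalidParameterError(
                f"state {seg.state!r} not valid for the pole-track simulator")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pole = config.pole
    fr = config.frame_rate
    dtf = 1.0 / fr

    frames, events = [], []
    t0 = 0.0
    phase = 0.0
    last = np.zeros(2)
    for seg in schedule:
        n = _frames_of(seg.duration, fr)
        tt = np.arange(1, n + 1) * dtf
        if seg.state == "long_axis_rotation":
            f = float(seg.params.get("freq", pole.freq_ccw_mean))
            direction = seg.params.get("direction", "CCW")
            if f > fr / 4.0:
                raise AliasingError(
                    f"pole frequency {f} Hz needs frame_rate >= {4 * f} Hz")
            amp = float(seg.params.get("amplitude", pole.amplitude))
            s = 1.0 if direction == "CCW" else -1.0
            ph = phase + s * 2.0 * math.pi * f * tt
            pos = np.column_stack([amp * np.cos(ph), amp * np.sin(ph)])
            phase = float(ph[-1] % (2.0 * math.pi))
            events.append(Event("long_axis_rotation", t0, t0 + n * dtf,
                                {"freq_hz": f, "direction": direction,
                                 "amplitude_um": amp}))
        elif seg.state == "bending":
            amp = float(seg.params.get("bend_amplitude", pole.bend_amplitude))
            fb = float(seg.params.get("bend_freq", pole.bend_freq))
            psi = float(seg.params.get("bend_axis", 0.0))
            u = np.array([math.cos(psi), math.sin(psi)])
            pos = amp * np.sin(2.0 * math.pi * fb * tt)[:, None] * u
            events.append(Event("bending", t0, t0 + n * dtf,
                                {"bend_amplitude_um": amp, "bend_freq_hz": fb}))
        else:  # released: rotating motion hands over to ballistic drift
            speed = float(seg.params.get("speed", config.swim.v_push))
            heading = float(seg.params.get("heading",
                                           rng.uniform(0, 2 * math.pi)))
            u = np.array([math.cos(heading), math.sin(heading)])
            pos = last + speed * tt[:, None] * u
            events.append(Event("released", t0, t0 + n * dtf,
                                {"speed_um_s": speed}))
        t0 += n * dtf
        last = pos[-1]
        frames.append(pos)
    positions = np.vstack(frames)
    if pole.noise > 0 and noise_scale > 0:
        positions = positions + (pole.noise * noise_scale
                                 * rng.standard_normal(positions.shape))
    times = np.arange(1, len(positions) + 1) * dtf
    track = PoleTrack(times, positions, fr,
                      aux={"scenario": "pole", "seed": config.seed})
    return track, EventTable(events)


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def render_image_stack(
    traj: Trajectory,
    pixel_size: float = 0.1,
    spot_sigma: float = 2.0,
    snr: float = np.inf,
    shape: tuple[int, int] | None = None,
    origin: tuple[float, float] | None = None,
    amplitude: float = 8000.0,
    background: float = 400.0,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render the bead as a Gaussian spot in a 16-bit image stack.

    Pixel convention: pixel centres at integer coordinates, origin at the
    top-left pixel centre, x = column, y = row; the synthetic frames are
    generated and tracked in the same orientation, so px <-> µm conversion
    is a pure scale + offset.  SNR = amplitude / Gaussian noise sigma.
    ``origin`` is the µm position of pixel (0, 0); by default the stack is
    framed around the trajectory with a 5*spot_sigma margin.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pos_px = traj.positions / pixel_size
    margin = 5.0 * spot_sigma
    if origin is None:
        ox = float(np.floor(pos_px[:, 0].min() - margin))
        oy = float(np.floor(pos_px[:, 1].min() - margin))
    else:
        ox, oy = origin[0] / pixel_size, origin[1] / pixel_size
    cols = pos_px[:, 0] - ox
    rows = pos_px[:, 1] - oy
    if shape is None:
        shape = (int(np.ceil(rows.max() + margin)) + 1,
                 int(np.ceil(cols.max() + margin)) + 1)
    h, w = shape
    lo = 3.0 * spot_sigma
    bad = np.flatnonzero((cols < lo) | (cols > w - 1 - lo)
                         | (rows < lo) | (rows > h - 1 - lo))
    if bad.size:
        raise FieldOfViewError(
            f"spot leaves the field of view in frames {bad[:20].tolist()}"
            + ("..." if bad.size > 20 else ""))
    rgrid = np.arange(h)[:, None]
    cgrid = np.arange(w)[None, :]
    stack = np.empty((len(traj), h, w), dtype=np.uint16)
    inv2s2 = 1.0 / (2.0 * spot_sigma ** 2)
    noise_sd = amplitude / snr if np.isfinite(snr) and snr > 0 else 0.0
    for i, (cc, rr) in enumerate(zip(cols, rows)):
        img = background + amplitude * np.exp(
            -((cgrid - cc) ** 2 + (rgrid - rr) ** 2) * inv2s2)
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal(img.shape)
        np.clip(img, 0, 65535, out=img)
        stack[i] = img.round().astype(np.uint16)
    return ImageStack(stack, pixel_size, traj.frame_rate, 16,
                      origin_um=(ox * pixel_size, oy * pixel_size))


# ---------------------------------------------------------------------------
# Schedule builders for the study conditions
# ---------------------------------------------------------------------------


def pilus_interleaved_schedule(
    rng: np.random.Generator,
    n_cycles: int,
    cycle_dist,
    intercycle_dist,
    flagellum: bool = True,
) -> BehaviorSchedule:
    """Alternate pilus attachment cycles with inter-cycle activity.

    Between cycles the bead gyrates when the flagellum is present, and shows
    only Brownian motion in the flagellum-less (hook deletion) condition.
    """
    inter_state = "gyration" if flagellum else "brownian"
    items = [(inter_state, float(intercycle_dist.rvs(random_state=rng)))]
    for i in range(n_cycles):
        items.append(("pilus_cycle", float(cycle_dist.rvs(random_state=rng))))
        items.append((inter_state, float(intercycle_dist.rvs(random_state=rng))))
    return BehaviorSchedule.from_durations(items)


def activity_schedule(
    rng: np.random.Generator,
    activity_dist,
    rotation_dist=None,
    lead: float = 5.0,
    tail: float = 15.0,
) -> tuple[BehaviorSchedule, dict]:
    """Flagellar-activity lifetime of one trapped predivisional cell.

    Brownian lead-in, gyration for the drawn activity duration (its trailing
    part replaced by the long-axis-rotation stage when ``rotation_dist`` is
    given), then terminal Brownian motion after cell separation.  Returns
    the schedule and the planted durations.
    """
    a = float(activity_dist.rvs(random_state=rng))
    planted = {"activity_s": a}
    items = [("brownian", lead)]
    if rotation_dist is not None:
        r = float(rotation_dist.rvs(random_state=rng))
        r = min(r, 0.8 * a)
        planted["rotation_stage_s"] = r
        items.append(("gyration", a - r))
        items.append(("long_axis_rotation", r))
    else:
        items.append(("gyration", a))
    items.append(("brownian", tail))
    return BehaviorSchedule.from_durations(items), planted


def pole_rotation_schedule(
    rng: np.random.Generator,
    f_ccw: float,
    f_cw: float,
    n_intervals: int = 4,
    interval_range: tuple[float, float] = (1.5, 3.5),
    start_ccw: bool = True,
) -> BehaviorSchedule:
    """Alternating-direction long-axis rotation intervals of one cell."""
    items = []
    ccw = start_ccw
    for _ in range(n_intervals):
        dur = float(rng.uniform(*interval_range))
        items.append(("long_axis_rotation", dur,
                      {"freq": f_ccw if ccw else f_cw,
                       "direction": "CCW" if ccw else "CW"}))
        ccw = not ccw
    return BehaviorSchedule.from_durations(items)
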