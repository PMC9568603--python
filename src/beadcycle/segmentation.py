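"""Behavioral-state segmentation of trapped-bead trajectories.

Each trajectory frame is classified as flagellar gyration, pilus
attachment, long-axis rotation (slowed gyration during septum softening)
or Brownian motion, using a windowed rule cascade on geometric features
rather than a latent-state model: the signatures are explicit (sustained
rotation about the trap centre vs. directed/held off-centre displacement
vs. isotropic fluctuation), and rules keep every decision auditable.

Pilus attachment cycles are then extracted with their four sub-phases
(attachment, retraction, hold, release); a window satisfying both the
pilus and the gyration rule is assigned to the pilus, because pilus
attachment arrests gyration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .models import (
    KB,
    Event,
    EventTable,
    InvalidParameterError,
    SummaryStats,
    Trajectory,
    TrapModel,
)

__all__ = ["FeatureSeries", "SegmentationThresholds", "PilusCycle",
           "compute_features", "classify_states", "extract_pilus_cycles",
           "summarize_events"]


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


@dataclass
class FeatureSeries:
    """Per-window geometric features of a trajectory about a centre.

    Windows are ``window`` seconds long with 50% overlap by default and
    cover the whole track.
    """

    centers: np.ndarray          # window centre times, s
    starts: np.ndarray           # window start frame indices
    stops: np.ndarray            # window stop frame indices (exclusive)
    mean_abs_omega: np.ndarray   # rad/s
    net_angle: np.ndarray        # signed net angular displacement, rad
    angle_consistency: np.ndarray  # fraction of angle steps with the net sign
    radial_mean: np.ndarray      # µm
    radial_velocity: np.ndarray  # µm/s, least-squares slope of r(t)
    radial_monotonicity: np.ndarray  # fraction of positive lagged r increments
    variance: np.ndarray         # var(x)+var(y), µm²
    directedness: np.ndarray     # net displacement / path length, in [0, 1]
    window: float = 0.5
    frame_rate: float = 0.0

    def __len__(self) -> int:
        return len(self.centers)


def compute_features(
    traj: Trajectory,
    center: np.ndarray,
    window: float = 0.5,
    overlap: float = 0.5,
    smooth_window: int = 7,
) -> FeatureSeries:
    """Windowed features: rotation, radial motion, confinement, directedness.

    Positions are Savitzky-Golay smoothed before the path-length and radial
    computations so localization/thermal noise does not dominate the path
    length.  Deterministic given its inputs.
    """
    nw = int(round(window * traj.frame_rate))
    if nw < 5:
        raise InvalidParameterError("window must span >= 5 frames")
    if len(traj) < nw:
        raise InvalidParameterError("track shorter than one window")
    hop = max(1, int(round(nw * (1.0 - overlap))))

    center = np.asarray(center, dtype=float)
    disp = traj.positions - center
    w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    if len(traj) >= w and w > 2:
        pos_s = savgol_filter(traj.positions, w, polyorder=2, axis=0)
    else:
        pos_s = traj.positions
    disp_s = pos_s - center
    r_s = np.hypot(disp_s[:, 0], disp_s[:, 1])
    theta = np.unwrap(np.arctan2(disp[:, 1], disp[:, 0]))
    dtheta = np.diff(theta)
    lag = max(1, nw // 5)
    dr_lag = r_s[lag:] - r_s[:-lag]

    starts = np.arange(0, len(traj) - nw + 1, hop)
    if starts[-1] + nw < len(traj):  # cover the tail
        starts = np.append(starts, len(traj) - nw)
    n = len(starts)
    out = {k: np.empty(n) for k in
           ("mean_abs_omega", "net_angle", "angle_consistency", "radial_mean",
            "radial_velocity", "radial_monotonicity", "variance",
            "directedness")}
    dt = traj.dt
    tloc = np.arange(nw) * dt
    tloc -= tloc.mean()
    denom_t = float(np.dot(tloc, tloc))
    for i, i0 in enumerate(starts):
        i1 = i0 + nw
        dth = dtheta[i0:i1 - 1]
        net = theta[i1 - 1] - theta[i0]
        out["net_angle"][i] = net
        out["mean_abs_omega"][i] = np.abs(net) / ((nw - 1) * dt) if nw > 1 else 0.0
        sgn = np.sign(net) if net != 0 else 1.0
        out["angle_consistency"][i] = float(np.mean(np.sign(dth) == sgn)) \
            if len(dth) else 0.0
        rwin = r_s[i0:i1]
        out["radial_mean"][i] = rwin.mean()
        out["radial_velocity"][i] = float(np.dot(tloc, rwin - rwin.mean())) / denom_t
        j0, j1 = i0, min(i1, len(dr_lag))
        seg = dr_lag[j0:j1]
        out["radial_monotonicity"][i] = float(np.mean(seg > 0)) if len(seg) else 0.5
        out["variance"][i] = float(traj.positions[i0:i1].var(axis=0).sum())
        netdisp = float(np.hypot(*(pos_s[i1 - 1] - pos_s[i0])))
        path = float(np.sum(np.hypot(*np.diff(pos_s[i0:i1], axis=0).T)))
        out["directedness"][i] = min(netdisp / path, 1.0) if path > 0 else 0.0
    centers = traj.times[starts] + (nw - 1) * dt / 2.0
    return FeatureSeries(centers, starts, starts + nw, window=window,
                         frame_rate=traj.frame_rate, **out)


# ---------------------------------------------------------------------------
# Rule cascade
# ---------------------------------------------------------------------------


@dataclass
class SegmentationThresholds:
    """Decision thresholds of the rule cascade (units: µm, s, rad, µm²).

    ``r_thresh`` separates "displaced out of the trap" from thermal
    excursions (default 3x the thermal SD per axis); ``hold_var`` flags the
    low-variance held state; the retraction regime is an outward radial
    velocity in [retract_vmin, retract_vmax] sustained in time
    (monotonicity); ``a_thresh`` is the net angular displacement per window
    that marks gyration.  ``omega_split_factor`` separates full-speed
    gyration from the slowed long-axis-rotation stage relative to the
    track's own gyration level.
    """

    r_thresh: float
    d_thresh: float = 0.7
    a_thresh: float = math.pi / 2.0
    min_duration: float = 0.4
    hold_var: float = 1e-3
    retract_vmin: float = 0.03
    retract_vmax: float = 1.0
    monotone_frac: float = 0.7
    consistency: float = 0.6
    omega_split_factor: float = 0.75
    r_floor: float = 0.05
    gyration_r_floor: float | None = None  # defaults to r_thresh

    def __post_init__(self) -> None:
        if self.r_thresh <= 0 or self.a_thresh <= 0:
            raise InvalidParameterError(
                "thresholds must be positive (unreachable states otherwise)")

    @classmethod
    def from_trap(cls, trap: TrapModel, **overrides) -> "SegmentationThresholds":
        """Noise-scaled defaults: r_thresh = 3*sqrt(k_B*T/kappa), etc."""
        kappa = float(np.mean(trap.kappa))
        sigma2 = KB * trap.temperature / kappa
        defaults = dict(
            r_thresh=3.0 * math.sqrt(sigma2),
            hold_var=sigma2,          # half the 2-D thermal variance 2*kT/kappa
            r_floor=math.sqrt(sigma2),
            gyration_r_floor=3.0 * math.sqrt(sigma2),
        )
        defaults.update(overrides)
        return cls(**defaults)


def _window_labels(features: FeatureSeries, thr: SegmentationThresholds
                   ) -> np.ndarray:
    f = features
    rotating = ((np.abs(f.net_angle) > thr.a_thresh)
                & (f.angle_consistency > thr.consistency))
    # pilus retraction is a linear drag: sustained outward radial motion
    # without net rotation (rotation at radius is gyration, not retraction)
    retracting = ((f.radial_velocity > thr.retract_vmin)
                  & (f.radial_velocity < thr.retract_vmax)
                  & (f.radial_monotonicity > thr.monotone_frac)
                  & ~rotating)
    holding = (f.variance < thr.hold_var) & (f.radial_mean > thr.r_thresh)
    directed = f.directedness > thr.d_thresh
    pilus = (f.radial_mean > thr.r_thresh) & (directed | retracting | holding)
    # a genuine orbit runs displaced out of the trap; angular diffusion near
    # the centre produces large apparent net angles without a real orbit
    gyr_floor = (thr.gyration_r_floor if thr.gyration_r_floor is not None
                 else thr.r_thresh)
    gyration = rotating & (f.radial_mean > gyr_floor)
    labels = np.full(len(f), "brownian", dtype=object)
    labels[gyration] = "gyration"
    labels[pilus] = "pilus_cycle"  # tie-break: pilus arrests gyration
    return labels


def _split_long_axis(labels: np.ndarray, features: FeatureSeries,
                     thr: SegmentationThresholds) -> np.ndarray:
    """Relabel slowed trailing gyration windows as long-axis rotation.

    The long-axis-rotation stage is gyration driven at a reduced force, so
    it appears as windows whose |angular velocity| falls well below the
    track's own full-gyration level.
    """
    gy = labels == "gyration"
    if gy.sum() < 4:
        return labels
    level = float(np.median(features.mean_abs_omega[gy]))
    slow = gy & (features.mean_abs_omega < thr.omega_split_factor * level)
    if slow.any() and not slow.all():
        labels = labels.copy()
        labels[slow] = "long_axis_rotation"
    return labels


def classify_states(
    features: FeatureSeries,
    thresholds: SegmentationThresholds,
    split_long_axis: bool = True,
) -> EventTable:
    """Window rule cascade -> per-frame labels -> merged state intervals.

    Frames take the label of the window whose centre is nearest; runs
    shorter than ``min_duration`` are merged into their longer neighbour
    (hysteresis), so brief threshold chatter does not fragment states.
    """
    labels = _window_labels(features, thresholds)
    if split_long_axis:
        labels = _split_long_axis(labels, features, thresholds)

    n_frames = int(features.stops[-1])
    frame_labels = np.empty(n_frames, dtype=object)
    win_centers_idx = (features.starts + features.stops - 1) / 2.0
    nearest = np.searchsorted(win_centers_idx,
                              np.arange(n_frames), side="left")
    nearest = np.clip(nearest, 0, len(labels) - 1)
    left = np.clip(nearest - 1, 0, len(labels) - 1)
    use_left = (np.abs(win_centers_idx[left] - np.arange(n_frames))
                <= np.abs(win_centers_idx[nearest] - np.arange(n_frames)))
    frame_labels = np.where(use_left, labels[left], labels[nearest])

    dt = 1.0 / features.frame_rate
    segs: list[list] = []
    for i, lab in enumerate(frame_labels):
        if segs and segs[-1][0] == lab:
            segs[-1][2] = i + 1
        else:
            segs.append([lab, i, i + 1])
    min_frames = max(1, int(round(thresholds.min_duration
                                  * features.frame_rate)))
    changed = True
    while changed and len(segs) > 1:
        changed = False
        lengths = [s[2] - s[1] for s in segs]
        k = int(np.argmin(lengths))
        if lengths[k] < min_frames:
            if k == 0:
                segs[1][1] = segs[0][1]
                segs.pop(0)
            elif k == len(segs) - 1:
                segs[-2][2] = segs[-1][2]
                segs.pop()
            else:
                lft, rgt = segs[k - 1], segs[k + 1]
                if (lft[2] - lft[1]) >= (rgt[2] - rgt[1]):
                    lft[2] = segs[k][2]
                else:
                    rgt[1] = segs[k][1]
                segs.pop(k)
            merged = []
            for s in segs:
                if merged and merged[-1][0] == s[0]:
                    merged[-1][2] = s[2]
                else:
                    merged.append(s)
            segs = merged
            changed = True
    t0 = 0.0  # event clock starts at the schedule origin
    events = [Event(str(lab), t0 + i0 * dt, t0 + i1 * dt)
              for lab, i0, i1 in segs]
    return EventTable(events)


# ---------------------------------------------------------------------------
# Pilus attachment cycles
# ---------------------------------------------------------------------------


@dataclass
class PilusCycle:
    """One attachment -> retraction -> hold -> release event.

    Invariants: attach < retract_end <= hold_end < release_end and the
    release speed exceeds the retraction speed (fast trap relaxation vs.
    slow motor retraction).  ``complete`` is False for censored cycles
    (no release before the track ends); ``resolved`` is False when the
    interval was too short to split into sub-phases.
    """

    attach: float
    retract_end: float
    hold_end: float
    release_end: float
    retract_speed: float
    release_speed: float
    anchor_bearing: float
    complete: bool = True
    resolved: bool = True

    @property
    def duration(self) -> float:
        return self.release_end - self.attach

    def __post_init__(self) -> None:
        if self.resolved and self.complete:
            if not (self.attach < self.retract_end <= self.hold_end
                    < self.release_end):
                raise InvalidParameterError("pilus sub-phases out of order")


def extract_pilus_cycles(
    events: EventTable,
    traj: Trajectory,
    center: np.ndarray | None = None,
    thresholds: SegmentationThresholds | None = None,
    smooth_window: int = 7,
) -> list[PilusCycle]:
    """Split classified pilus intervals into their four sub-phases.

    The attachment time is refined by walking backwards from the detected
    interval along the monotone outward ramp (window classification only
    fires once the bead is clearly displaced); the release time forward to
    where the radial distance has relaxed back.  Sub-phases are split on
    the sign/magnitude of the radial velocity: sustained outward =
    retraction, near-zero = hold, fast inward = release.
    """
    pilus_events = events.select("pilus_cycle")
    if not pilus_events:
        return []
    if center is None:
        center = np.zeros(2)
    if thresholds is None:
        thresholds = SegmentationThresholds(r_thresh=0.1)
    disp = traj.positions - np.asarray(center, dtype=float)
    w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
    r_s = savgol_filter(np.hypot(disp[:, 0], disp[:, 1]), w, polyorder=2) \
        if len(traj) >= w else np.hypot(disp[:, 0], disp[:, 1])
    dt = traj.dt
    # fine radial velocity resolves the fast release; the slow retraction
    # (~0.1 µm/s) sits below the frame-to-frame noise, so the retract/hold
    # boundary uses a velocity averaged on the 0.5 s scale instead
    v_r = np.gradient(r_s, dt)
    from scipy.ndimage import uniform_filter1d

    wc = max(3, int(round(0.5 * traj.frame_rate)))
    r_coarse = uniform_filter1d(r_s, size=wc, mode="nearest") \
        if len(r_s) >= wc else r_s
    lagc = max(1, int(round(0.25 * traj.frame_rate)))
    v_r_coarse = np.gradient(r_coarse, dt)
    v_r_coarse = uniform_filter1d(v_r_coarse, size=lagc, mode="nearest") \
        if len(v_r_coarse) >= lagc else v_r_coarse
    t = traj.times
    back_eps = 0.01

    cycles: list[PilusCycle] = []
    prev_stop = 0
    for ev in pilus_events:
        i0 = int(np.searchsorted(t, ev.start - 1e-9))
        i1 = min(int(np.searchsorted(t, ev.end - 1e-9)), len(t) - 1)
        # refine attachment: walk back along the outward ramp
        j = i0
        while (j > prev_stop and r_s[j - 1] <= r_s[j] + back_eps
               and r_s[j - 1] > thresholds.r_floor):
            j -= 1
        attach_idx = j
        # refine release end: walk forward until the bead has relaxed back
        # (radius near the thermal floor, or the fast inward run has ended)
        k = i1
        k_max = min(len(t) - 1, i1 + int(round(1.0 / dt)))
        complete = False
        seen_fast = False
        while k < k_max:
            if r_s[k] < 2.0 * thresholds.r_floor:
                complete = True
                break
            if v_r[k] < -thresholds.retract_vmax:
                seen_fast = True
            elif seen_fast and v_r[k] >= -thresholds.retract_vmin:
                complete = True
                break
            k += 1
        if not complete and k >= len(t) - 2:
            cycles.append(PilusCycle(t[attach_idx], t[i1], t[i1], t[k],
                                     0.0, 0.0, 0.0, complete=False,
                                     resolved=False))
            prev_stop = k
            continue
        release_end_idx = k

        n_win = max(1, int(round(0.5 * traj.frame_rate)))
        if (release_end_idx - attach_idx) < 3 * n_win:
            cycles.append(PilusCycle(t[attach_idx], t[attach_idx],
                                     t[attach_idx], t[release_end_idx],
                                     0.0, 0.0, 0.0, complete=True,
                                     resolved=False))
            prev_stop = release_end_idx
            continue

        seg = slice(attach_idx, release_end_idx + 1)
        vr_seg = v_r[seg]
        # release start: last sustained fast inward run
        fast_in = np.flatnonzero(vr_seg < -thresholds.retract_vmax)
        rel_start_local = fast_in[0] if fast_in.size else len(vr_seg) - 1
        # retraction end: coarse outward velocity falls below the hold level
        vrc_seg = v_r_coarse[seg]
        hold_lvl = thresholds.retract_vmin
        k2 = 0
        limit = rel_start_local
        run = 0
        need = max(2, int(round(0.25 * traj.frame_rate)))
        for m in range(limit):
            if vrc_seg[m] < hold_lvl:
                run += 1
                if run >= need and m - run >= 0:
                    k2 = m - run + 1
                    break
            else:
                run = 0
        else:
            k2 = limit
        retract_end_idx = attach_idx + max(1, k2)
        hold_end_idx = attach_idx + rel_start_local
        if hold_end_idx <= retract_end_idx:
            hold_end_idx = retract_end_idx
        dr = r_s[retract_end_idx] - r_s[attach_idx]
        dt_ret = t[retract_end_idx] - t[attach_idx]
        retract_speed = max(dr, 0.0) / dt_ret if dt_ret > 0 else 0.0
        release_speed = float(-vr_seg[rel_start_local:].min(initial=0.0))
        hold_slice = slice(retract_end_idx, max(hold_end_idx, retract_end_idx + 1))
        bearing = float(math.atan2(np.mean(disp[hold_slice, 1]),
                                   np.mean(disp[hold_slice, 0])))
        hold_end_t = t[hold_end_idx]
        if hold_end_t >= t[release_end_idx]:
            hold_end_t = t[release_end_idx] - dt
        cycles.append(PilusCycle(
            t[attach_idx], t[retract_end_idx], hold_end_t,
            t[release_end_idx], retract_speed, release_speed, bearing))
        prev_stop = release_end_idx
    return cycles


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def summarize_events(
    events: EventTable,
    cycles: list[PilusCycle] | None = None,
) -> SummaryStats:
    """Aggregate one track's behavioral timeline.

    Reports mean ± SD of pilus-cycle durations and inter-cycle periods,
    the pili vs. flagellum time partition (pili time over pili + flagellar
    time, where flagellar time includes the long-axis-rotation stage), the
    overall flagellar-activity duration (onset of gyration to the
    transition into the terminal Brownian interval) and the
    long-axis-rotation stage duration.  Empty categories are absent from
    the result, never reported as zero.
    """
    stats = SummaryStats()
    cycles = [c for c in (cycles or []) if c.complete]
    if cycles:
        stats.add("pilus_cycle_duration_s", [c.duration for c in cycles])
        gaps = [b.attach - a.release_end
                for a, b in zip(cycles, cycles[1:]) if b.attach > a.release_end]
        stats.add("pilus_intercycle_s", gaps)
        resolved = [c for c in cycles if c.resolved]
        stats.add("pilus_retract_speed_um_s",
                  [c.retract_speed for c in resolved])
        stats.add("pilus_release_speed_um_s",
                  [c.release_speed for c in resolved])

    pili_t = events.state_time("pilus_cycle")
    flag_t = events.state_time("gyration", "long_axis_rotation")
    total = pili_t + flag_t
    if total > 0:
        stats["time_fraction_pili"] = pili_t / total
        stats["time_fraction_flagellum"] = flag_t / total
    covered = events.state_time(*{e.state for e in events})
    if covered > 0:
        stats["state_fractions"] = {
            s: events.state_time(s) / covered
            for s in sorted({e.state for e in events})}

    flagellar = events.select("gyration", "long_axis_rotation")
    evs = events.events
    if flagellar and evs[-1].state == "brownian" and len(evs) > 1:
        onset = flagellar[0].start
        separation = evs[-1].start
        if separation > onset:
            stats.add("activity_duration_s", [separation - onset])
    rot = events.select("long_axis_rotation")
    if rot:
        stats.add("rotation_stage_s", [e.duration for e in rot])
        # total time in the stage; robust when brief misclassified windows
        # split one physical stage into adjacent intervals
        stats.add("rotation_stage_total_s", [sum(e.duration for e in rot)])
    return stats
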