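"""Push/pull swimming statistics and pole-rotation analysis.

For the free bacteria-on-a-bead, forward swimming (push) means the
flagellated pole trails the bead (CW motor rotation) and is defined as a
positive velocity projection on the pole-to-bead body axis; backward
swimming (pull, CCW motor) is the negative projection.  For
surface-attached predivisional cells, the long-axis rotation of the
daughter compartment is read out from the quadrature x/y signal of the
flagellated pole: the spectral peak gives the frequency, the sign of the
mean cross-quadrature <x*dy/dt - y*dx/dt> the direction (positive = CCW).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .models import (
    EventTable,
    InvalidParameterError,
    PoleTrack,
    SummaryStats,
    Trajectory,
)

__all__ = ["SwimSequence", "RotationEstimate", "classify_swim_sequences",
           "swim_statistics", "rotation_frequency", "bending_metrics"]


@dataclass
class SwimSequence:
    """One uninterrupted swimming run in one direction."""

    direction: str       # "push" (forward) or "pull" (backward)
    start: float
    end: float
    mean_speed: float    # µm/s

    def __post_init__(self) -> None:
        if self.direction not in ("push", "pull"):
            raise InvalidParameterError("direction must be push or pull")
        if self.end <= self.start:
            raise InvalidParameterError("sequence duration must be positive")
        if self.mean_speed < 0:
            raise InvalidParameterError("speed must be >= 0")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RotationEstimate:
    """Rotation frequency/direction of one long-axis rotation interval."""

    start: float
    end: float
    frequency: float     # Hz
    direction: str       # "CW" or "CCW"
    amplitude: float     # µm

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InvalidParameterError("frequency must be positive")
        if self.direction not in ("CW", "CCW"):
            raise InvalidParameterError("direction must be CW or CCW")


# ---------------------------------------------------------------------------
# Push/pull classification
# ---------------------------------------------------------------------------


def _estimate_axis(traj: Trajectory, smooth_window: int = 5) -> np.ndarray:
    """Body axis estimated as the sign-continuous smoothed motion direction.

    The axis is only defined up to a global sign in this mode; the caller's
    direction labels are then consistent but may be globally swapped.
    """
    v = np.gradient(traj.positions, traj.dt, axis=0)
    if smooth_window > 2 and len(traj) >= smooth_window:
        w = smooth_window if smooth_window % 2 == 1 else smooth_window + 1
        from scipy.signal import savgol_filter

        v = savgol_filter(traj.positions, w, polyorder=2, deriv=1,
                          delta=traj.dt, axis=0)
    norm = np.hypot(v[:, 0], v[:, 1])
    bad = norm < 1e-12
    if bad.all():
        raise InvalidParameterError(
            "cannot estimate a body axis from a static trajectory")
    axis = v / np.maximum(norm[:, None], 1e-300)
    axis[bad] = 0.0
    # enforce sign continuity (the body axis does not flip at reversals)
    for i in range(1, len(axis)):
        if np.dot(axis[i], axis[i - 1]) < 0:
            axis[i] = -axis[i]
        if bad[i]:
            axis[i] = axis[i - 1]
    return axis


def classify_swim_sequences(
    traj: Trajectory,
    axis: np.ndarray | None = None,
    speed_floor: float = 2.0,
    max_gap: float = 0.5,
) -> list[SwimSequence]:
    """Segment a swimmer trajectory into push/pull sequences.

    ``axis`` is the per-frame pole-to-bead unit vector (ground truth from
    the simulator, ``traj.aux['axis']``, or estimated from the smoothed
    heading when absent).  Velocity is the per-interval displacement rate;
    its projection on the axis defines the direction (positive = push).
    Contiguous same-sign runs above ``speed_floor`` become sequences;
    sub-floor gaps shorter than ``max_gap`` seconds between same-sign runs
    are bridged, longer gaps are excluded from any sequence.
    """
    if axis is None:
        axis = traj.aux.get("axis")
    if axis is None:
        axis = _estimate_axis(traj)
    axis = np.asarray(axis, dtype=float)
    if axis.shape != traj.positions.shape:
        raise InvalidParameterError("axis must match the trajectory shape")

    dt = traj.dt
    # velocity of interval i = displacement from frame i to i+1
    v = np.diff(traj.positions, axis=0) / dt
    ax_mid = axis[:-1]
    proj = np.einsum("ij,ij->i", v, ax_mid)
    moving = np.abs(proj) > speed_floor
    sign = np.sign(proj)
    if len(proj) >= 3:
        # a single-frame sign island of modest magnitude is a noise blip,
        # not a genuine reversal (those project at full swimming speed)
        blip = (moving[1:-1]
                & (sign[1:-1] != sign[:-2]) & (sign[1:-1] != sign[2:])
                & (sign[:-2] == sign[2:])
                & (np.abs(proj[1:-1]) < 2.0 * speed_floor))
        moving[1:-1][blip] = False

    runs: list[list] = []  # [sign, i0, i1)
    for i in range(len(proj)):
        if not moving[i]:
            continue
        if runs and runs[-1][0] == sign[i] and runs[-1][2] == i:
            runs[-1][2] = i + 1
        elif (runs and runs[-1][0] == sign[i]
              and (i - runs[-1][2]) * dt <= max_gap
              and not np.any(moving[runs[-1][2]:i])):
            runs[-1][2] = i + 1  # bridge a brief sub-floor gap
        else:
            runs.append([sign[i], i, i + 1])
    seqs = []
    for s, i0, i1 in runs:
        sel = slice(i0, i1)
        msel = moving[sel]
        speeds = np.abs(proj[sel][msel]) if msel.any() else np.abs(proj[sel])
        seqs.append(SwimSequence(
            "push" if s > 0 else "pull",
            start=traj.times[i0], end=traj.times[i1],
            mean_speed=float(speeds.mean())))
    return seqs


def swim_statistics(seqs: list[SwimSequence]) -> SummaryStats:
    """Per-direction duration/speed aggregates plus count and time fractions.

    Both the count fraction and the time fraction of pushing are reported,
    since "fraction of sequences" is ambiguous between the two readings.
    Missing directions are absent from the result, not zero.
    """
    if not seqs:
        raise InvalidParameterError("need >= 1 sequence")
    stats = SummaryStats()
    for d in ("push", "pull"):
        sub = [s for s in seqs if s.direction == d]
        stats.add(f"{d}_duration_s", [s.duration for s in sub])
        stats.add(f"{d}_speed_um_s", [s.mean_speed for s in sub])
    n = len(seqs)
    t_push = sum(s.duration for s in seqs if s.direction == "push")
    t_all = sum(s.duration for s in seqs)
    stats["count_fraction_push"] = sum(
        1 for s in seqs if s.direction == "push") / n
    if t_all > 0:
        stats["time_fraction_push"] = t_push / t_all
    return stats


# ---------------------------------------------------------------------------
# Pole rotation frequency and direction
# ---------------------------------------------------------------------------


def _peak_frequency(x: np.ndarray, fs: float, pad: int = 8) -> tuple[float, float]:
    """Zero-padded periodogram peak with parabolic interpolation.

    Returns (frequency, peak-to-median power ratio).
    """
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** math.ceil(math.log2(max(n * pad, 16))))
    f, p = signal.periodogram(x, fs=fs, nfft=nfft, window="hann",
                              detrend="constant")
    if len(p) < 4:
        return 0.0, 0.0
    k = int(np.argmax(p[1:])) + 1
    if 1 <= k < len(p) - 1 and p[k] > 0:
        # parabolic refinement on log power
        logs = np.log(np.maximum(p[k - 1:k + 2], 1e-300))
        denom = logs[0] - 2 * logs[1] + logs[2]
        delta = 0.5 * (logs[0] - logs[2]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = float(f[k] + delta * (f[1] - f[0]))
    ratio = float(p[k] / max(np.median(p[1:]), 1e-300))
    return freq, ratio


def _direction_sign(x: np.ndarray, y: np.ndarray, dt: float) -> float:
    """Sign of the mean cross-quadrature <x*dy - y*dx>; positive = CCW."""
    xc, yc = x - x.mean(), y - y.mean()
    dx = np.gradient(xc, dt)
    dy = np.gradient(yc, dt)
    return float(np.sign(np.mean(xc * dy - yc * dx)))


def rotation_frequency(
    pole: PoleTrack | Trajectory,
    window: float = 0.5,
    overlap: float = 0.5,
    min_peak_ratio: float = 6.0,
    merge_tol: float = 0.2,
    min_windows: int = 2,
) -> list[RotationEstimate]:
    """Sliding-window rotation analysis of a flagellated-pole track.

    Each window yields a spectral-peak frequency of x(t) and a direction
    from the cross-quadrature sign; windows whose peak does not stand
    ``min_peak_ratio`` above the noise floor are left unclassified.
    Adjacent classified windows with the same direction and frequencies
    within ``merge_tol`` (relative) merge into intervals; each interval's
    frequency is then re-estimated over its full span.  Intervals supported
    by fewer than ``min_windows`` windows are dropped: single windows that
    straddle a direction switch carry a mixed spectrum and unreliable
    direction.
    """
    fs = pole.frame_rate
    nw = int(round(window * fs))
    if nw < 8 or len(pole) < nw:
        raise InvalidParameterError("track shorter than one analysis window")
    hop = max(1, int(round(nw * (1.0 - overlap))))
    x = pole.positions[:, 0]
    y = pole.positions[:, 1]
    dt = 1.0 / fs

    wins = []
    for i0 in range(0, len(x) - nw + 1, hop):
        i1 = i0 + nw
        freq, ratio = _peak_frequency(x[i0:i1], fs)
        if ratio < min_peak_ratio or freq <= 0 or freq >= fs / 2:
            wins.append(None)
            continue
        s = _direction_sign(x[i0:i1], y[i0:i1], dt)
        direction = "CCW" if s >= 0 else "CW"
        wins.append((i0, i1, freq, direction))

    estimates: list[RotationEstimate] = []
    cur = None
    for wrec in wins + [None]:
        if wrec is not None and cur is not None:
            i0, i1, freq, direction = wrec
            if (direction == cur["direction"]
                    and abs(freq - cur["freq"]) <= merge_tol * cur["freq"]):
                cur["i1"] = i1
                cur["freq"] = 0.5 * (cur["freq"] + freq)
                cur["count"] += 1
                continue
        if cur is not None and cur["count"] >= min_windows:
            estimates.append(_finalize_interval(x, y, cur, fs, dt))
        cur = None
        if wrec is not None:
            i0, i1, freq, direction = wrec
            cur = {"i0": i0, "i1": i1, "freq": freq, "direction": direction,
                   "count": 1}
    return [e for e in estimates if e is not None]


def _finalize_interval(x, y, cur, fs, dt) -> RotationEstimate | None:
    i0, i1 = cur["i0"], cur["i1"]
    freq, _ = _peak_frequency(x[i0:i1], fs)
    if freq <= 0:
        return None
    s = _direction_sign(x[i0:i1], y[i0:i1], dt)
    xc = x[i0:i1] - x[i0:i1].mean()
    yc = y[i0:i1] - y[i0:i1].mean()
    amp = float(np.sqrt(2.0) * np.sqrt(np.var(xc)))  # A for x = A cos
    return RotationEstimate(i0 * dt, i1 * dt, freq,
                            "CCW" if s >= 0 else "CW", amp)


# ---------------------------------------------------------------------------
# Bending
# ---------------------------------------------------------------------------


def bending_metrics(
    pole: PoleTrack | Trajectory,
    events: EventTable,
) -> dict | None:
    """Amplitude and duration of the pre-separation bending stage.

    Amplitude is the maximal displacement of the flagellated pole from its
    pre-onset baseline during the bending interval; returns None (absent,
    not zero) when the track has no bending interval.
    """
    bends = events.select("bending")
    if not bends:
        return None
    ev = bends[0]
    t = pole.times
    pre = t < ev.start - 1e-9
    baseline = pole.positions[pre].mean(axis=0) if pre.any() \
        else np.zeros(2)
    mask = (t >= ev.start - 1e-9) & (t <= ev.end + 1e-9)
    disp = np.hypot(*(pole.positions[mask] - baseline).T)
    return {
        "amplitude_um": float(disp.max()),
        "duration_s": float(sum(e.duration for e in bends)),
    }


def sequences_to_frame(seqs: list[SwimSequence]) -> pd.DataFrame:
    return pd.DataFrame([{
        "direction": s.direction, "start_s": s.start, "end_s": s.end,
        "duration_s": s.duration, "mean_speed_um_s": s.mean_speed}
        for s in seqs])


def rotations_to_frame(ests: list[RotationEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start_s": e.start, "end_s": e.end, "frequency_hz": e.frequency,
        "direction": e.direction, "amplitude_um": e.amplitude}
        for e in ests])
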