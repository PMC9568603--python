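"""Force inference for a calibrated trapped-bead trajectory.

The instantaneous trap restoring force is F = kappa * (center - x); its
decomposition about the trap centre gives the radial component (signed,
negative = pulling the bead back inward) and tangential component.  The net
rotational force generated by the flagellum follows from the overdamped
drag balance at the bead, F_rot = gamma_eff * <|omega|> * <r> over gyration
frames; the maximal translational force is kappa times the maximal radial
displacement.  gamma_eff defaults to the bead-only Stokes drag, a declared
lower bound because the attached cell contributes unmodeled drag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .models import (
    BeadGeometry,
    EventTable,
    InvalidParameterError,
    Trajectory,
    TrapModel,
)

__all__ = ["ForceSeries", "ForceSummary", "displacement_force",
           "summarize_forces"]


@dataclass
class ForceSeries:
    """Per-frame trap force and its polar decomposition about the centre."""

    times: np.ndarray
    force: np.ndarray           # (n, 2), pN
    radial: np.ndarray          # signed radial component (outward positive)
    tangential: np.ndarray      # signed tangential component (CCW positive)
    angular_velocity: np.ndarray  # rad/s about the trap centre
    radius: np.ndarray          # µm, distance from centre
    undefined: np.ndarray       # frames at the exact centre (flagged)
    frame_rate: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.times,
            "fx_pN": self.force[:, 0],
            "fy_pN": self.force[:, 1],
            "f_radial_pN": self.radial,
            "f_tangential_pN": self.tangential,
            "omega_rad_s": self.angular_velocity,
            "r_um": self.radius,
            "undefined": self.undefined,
        })


@dataclass
class ForceSummary:
    """Headline forces: net rotational and maximal translational.

    ``f_rot`` is None (absent, not zero) when no gyration interval was
    supplied.
    """

    f_rot: float | None
    f_trans_max: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f_rot is not None and self.f_rot < 0:
            raise InvalidParameterError("F_rot must be >= 0")
        if self.f_trans_max < 0:
            raise InvalidParameterError("F_trans_max must be >= 0")


def _smooth_derivative(x: np.ndarray, dt: float, window: int) -> np.ndarray:
    """Savitzky-Golay first derivative; centred differences when window<=1."""
    if window and window > 2 and len(x) >= window:
        w = window if window % 2 == 1 else window + 1
        return savgol_filter(x, w, polyorder=2, deriv=1, delta=dt)
    return np.gradient(x, dt)


def displacement_force(
    traj: Trajectory,
    trap: TrapModel,
    smooth_window: int = 5,
) -> ForceSeries:
    """Per-frame trap force kappa*(center - x) and polar decomposition.

    The signed angular velocity about the trap centre is computed from the
    unwrapped polar angle with a Savitzky-Golay derivative (``smooth_window``
    frames, default 5; pass 0 for raw centred differences).  Frames at the
    exact centre have an undefined tangent; their angular velocity is set to
    0 and flagged.
    """
    disp = traj.positions - trap.center
    force = -trap.kappa * disp  # kappa*(center - x)
    r = np.hypot(disp[:, 0], disp[:, 1])
    undefined = r < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        ur = np.where(r[:, None] > 1e-12, disp / np.maximum(r[:, None], 1e-300),
                      0.0)
    radial = np.einsum("ij,ij->i", force, ur)
    # tangential unit vector (CCW): (-ur_y, ur_x)
    tangential = force[:, 1] * ur[:, 0] - force[:, 0] * ur[:, 1]
    theta = np.unwrap(np.arctan2(disp[:, 1], disp[:, 0]))
    omega = _smooth_derivative(theta, traj.dt, smooth_window)
    omega = np.where(undefined, 0.0, omega)
    # |F|^2 == radial^2 + tangential^2 holds per construction
    return ForceSeries(traj.times, force, radial, tangential, omega, r,
                       undefined, traj.frame_rate)


def summarize_forces(
    fs: ForceSeries,
    geometry: BeadGeometry,
    events: EventTable | None,
    kappa: float | np.ndarray | None = None,
    gamma_effective: float | None = None,
    quantile: float = 0.95,
    smooth_time: float = 0.5,
) -> ForceSummary:
    """Net rotational and maximal translational force of the track.

    F_rot = gamma_eff * <|omega|> * <r> over frames inside gyration
    intervals (drag balance of the tangential driving).  F_trans_max =
    kappa * Q(r_bar, quantile), where r_bar is the radial displacement
    averaged over ``smooth_time`` seconds: the maximal translational force
    is a sustained plateau (a held or orbiting bead), and the raw max of
    the unsmoothed series is an extreme-value statistic biased upward by
    thermal noise.  ``quantile=1.0`` with ``smooth_time=0`` recovers the
    raw maximum.  ``kappa`` defaults to the magnitude of the per-frame
    force over radius.
    """
    if not 0 < quantile <= 1:
        raise InvalidParameterError("quantile must be in (0, 1]")
    gamma = gamma_effective if gamma_effective is not None else geometry.drag
    if kappa is None:
        ok = fs.radius > 1e-9
        if not np.any(ok):
            raise InvalidParameterError("cannot infer kappa from a centred track")
        kappa_val = float(np.median(
            np.hypot(fs.force[ok, 0], fs.force[ok, 1]) / fs.radius[ok]))
    else:
        kappa_val = float(np.mean(kappa))

    r = fs.radius
    w = int(round(smooth_time * fs.frame_rate)) if fs.frame_rate > 0 else 0
    if w > 2 and len(r) >= w:
        from scipy.ndimage import uniform_filter1d

        r_s = uniform_filter1d(r, size=w, mode="nearest")
    else:
        r_s = r
    f_trans_max = kappa_val * float(np.quantile(r_s, quantile))

    f_rot = None
    extras: dict = {"kappa": kappa_val, "gamma_effective": gamma}
    if events is not None:
        gy = events.select("gyration")
        if gy:
            mask = np.zeros(len(fs.times), dtype=bool)
            for e in gy:
                mask |= (fs.times >= e.start - 1e-9) & (fs.times <= e.end + 1e-9)
            mask &= ~fs.undefined
            if mask.sum() >= 2:
                mean_abs_omega = float(np.mean(np.abs(
                    fs.angular_velocity[mask])))
                mean_r = float(np.mean(r[mask]))
                f_rot = gamma * mean_abs_omega * mean_r
                extras.update({"mean_abs_omega": mean_abs_omega,
                               "mean_radius": mean_r,
                               "n_gyration_frames": int(mask.sum())})
    return ForceSummary(f_rot, f_trans_max, extras)
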