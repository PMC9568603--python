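"""Trap-stiffness calibration from a quiescent (Brownian-only) segment.

Two standard estimators of the thermal-fluctuation calibration:

* equipartition: kappa = k_B*T / var(x) per axis;
* power spectrum: Lorentzian fit S(f) = D/(2*pi^2*(f_c^2 + f^2)) to the
  one-sided spectrum, kappa = 2*pi*gamma*f_c.

Confidence intervals for the equipartition estimate come from a
moving-block bootstrap with block length 10x the relaxation time, because
consecutive samples of a trapped bead are strongly autocorrelated and an
i.i.d. bootstrap would understate the CI.  No camera-blur or aliasing
corrections are applied (the synthetic data are not blurred); for real
camera data these corrections matter at high corner frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .models import KB, InvalidParameterError, Trajectory

__all__ = ["CalibrationResult", "stiffness_equipartition", "stiffness_psd"]

#: Samples below which equipartition calibration is refused outright.
MIN_SAMPLES = 100
#: Samples recommended for acceptance-grade estimates.
RECOMMENDED_SAMPLES = 10_000


@dataclass
class CalibrationResult:
    """Per-axis stiffness estimate with bootstrap/fit uncertainty."""

    kappa_x: float
    kappa_y: float
    method: str
    n_samples: int
    ci_half_width_x: float = float("nan")
    ci_half_width_y: float = float("nan")
    reliable: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa_x <= 0 or self.kappa_y <= 0:
            raise InvalidParameterError("stiffness estimates must be positive")

    @property
    def kappa(self) -> np.ndarray:
        return np.array([self.kappa_x, self.kappa_y])


def _autocorr_time(x: np.ndarray, dt: float) -> float:
    """Relaxation time from the lag where the ACF first drops below 1/e."""
    x = x - x.mean()
    n = len(x)
    nmax = min(n - 1, 5000)
    var = float(np.dot(x, x)) / n
    if var <= 0:
        return dt
    target = var / math.e
    for lag in range(1, nmax):
        c = float(np.dot(x[:-lag], x[lag:])) / n
        if c < target:
            # linear interpolation between lag-1 and lag
            prev = float(np.dot(x[:-(lag - 1)], x[lag - 1:])) / n if lag > 1 else var
            frac = (prev - target) / max(prev - c, 1e-30)
            return dt * ((lag - 1) + frac)
    return dt * nmax


def stiffness_equipartition(
    traj: Trajectory,
    temperature: float,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> CalibrationResult:
    """Equipartition calibration: kappa = k_B*T / sample variance per axis.

    The trajectory must be Brownian-only (caller-asserted).  The mean is
    subtracted per axis.  CI half-widths are 1.96x the moving-block
    bootstrap SD of the stiffness, block length = 10x the estimated
    relaxation time.
    """
    n = len(traj)
    if n < MIN_SAMPLES:
        raise InvalidParameterError(
            f"refusing to calibrate on {n} samples (< {MIN_SAMPLES})")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    kt = KB * temperature
    pos = traj.positions - traj.positions.mean(axis=0)
    var = pos.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise InvalidParameterError("zero positional variance; cannot calibrate")
    kappa = kt / var

    ci = np.full(2, np.nan)
    if n_boot > 0:
        for ax in range(2):
            tau = _autocorr_time(pos[:, ax], traj.dt)
            block = max(1, int(round(10.0 * tau / traj.dt)))
            block = min(block, n // 2)
            n_blocks = int(math.ceil(n / block))
            starts = rng.integers(0, n - block + 1, size=(n_boot, n_blocks))
            est = np.empty(n_boot)
            x = pos[:, ax]
            idx = np.arange(block)
            for b in range(n_boot):
                sample = x[(starts[b][:, None] + idx[None, :]).ravel()[:n]]
                est[b] = kt / sample.var(ddof=1)
            ci[ax] = 1.96 * est.std(ddof=1)
    return CalibrationResult(float(kappa[0]), float(kappa[1]),
                             "equipartition", n,
                             float(ci[0]), float(ci[1]),
                             reliable=n >= RECOMMENDED_SAMPLES,
                             extras={"variance": var.tolist()})


def _lorentzian(f: np.ndarray, d: float, fc: float) -> np.ndarray:
    return d / (2.0 * math.pi ** 2 * (fc ** 2 + f ** 2))


def stiffness_psd(
    traj: Trajectory,
    temperature: float,
    drag: float,
    nperseg: int | None = None,
    fmax: float | None = None,
) -> CalibrationResult:
    """Power-spectrum calibration: Lorentzian corner-frequency fit per axis.

    Welch one-sided spectra are fitted with S(f) = D/(2*pi^2*(f_c^2+f^2));
    kappa = 2*pi*gamma*f_c.  Flagged unreliable when the fit fails or the
    corner frequency exceeds a quarter of the sampling rate (undersampled
    Lorentzian knee).
    """
    n = len(traj)
    if n < MIN_SAMPLES:
        raise InvalidParameterError(
            f"refusing to calibrate on {n} samples (< {MIN_SAMPLES})")
    if drag <= 0:
        raise InvalidParameterError("drag must be positive")
    fs = traj.frame_rate
    if nperseg is None:
        nperseg = min(n, 8192)
    d0 = KB * temperature / drag
    kappas, fcs, reliable = [], [], True
    for ax in range(2):
        x = traj.positions[:, ax] - traj.positions[:, ax].mean()
        f, s = signal.welch(x, fs=fs, nperseg=nperseg, detrend="constant")
        keep = f > 0
        # the sampled spectrum folds power from beyond Nyquist onto the
        # tail; fit only well below Nyquist where aliasing is negligible
        keep &= f <= (fmax if fmax is not None else fs / 8.0)
        f, s = f[keep], s[keep]
        # half-power heuristic for the initial corner frequency
        s0 = float(np.median(s[: max(3, len(s) // 100)]))
        fc0 = math.sqrt(max(d0 / (2.0 * math.pi ** 2 * s0), 1e-12))
        try:
            popt, _ = optimize.curve_fit(
                _lorentzian, f, s, p0=[d0, fc0],
                sigma=s, absolute_sigma=False,
                bounds=([0.0, 1e-9], [np.inf, fs]), maxfev=20000)
            d_fit, fc = float(popt[0]), float(popt[1])
        except RuntimeError:
            d_fit, fc = d0, fc0
            reliable = False
        if fc > fs / 4.0 or fc <= 1e-6:
            reliable = False
        fcs.append(fc)
        kappas.append(2.0 * math.pi * drag * fc)
    return CalibrationResult(kappas[0], kappas[1], "psd", n,
                             reliable=reliable and n >= RECOMMENDED_SAMPLES,
                             extras={"corner_frequency": fcs,
                                     "diffusion": d0})
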