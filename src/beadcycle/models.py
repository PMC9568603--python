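"""Core data types and physical constants.

Unit system used throughout the package: micrometres (µm), seconds (s),
piconewtons (pN), hertz (Hz), kelvin (K).  Derived units follow: stiffness in
pN/µm, drag in pN·s/µm, diffusivity in µm²/s, dynamic viscosity in pN·s/µm²
(1 Pa·s = 1 pN·s/µm², so water at 30 °C is ~1e-3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Iterator

import numpy as np
import pandas as pd

#: Boltzmann constant in pN·µm/K.
KB = 1.380649e-5

#: Default absolute temperature (30 °C growth/assay conditions).
DEFAULT_TEMPERATURE = 303.15

#: Default dynamic viscosity of the aqueous medium, pN·s/µm².
DEFAULT_VISCOSITY = 1.0e-3


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its invariant."""


# ---------------------------------------------------------------------------
# Trap and bead
# ---------------------------------------------------------------------------


@dataclass
class TrapModel:
    """Harmonic optical trap: restoring force F = kappa * (center - x).

    Parameters
    ----------
    kappa_x, kappa_y:
        Trap stiffness per axis, pN/µm.  Must be positive.
    center:
        Trap centre in the image plane, µm.
    temperature:
        Bath temperature, K.
    """

    kappa_x: float
    kappa_y: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if self.kappa_x <= 0 or self.kappa_y <= 0:
            raise InvalidParameterError("trap stiffness must be positive")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")

    @property
    def kappa(self) -> np.ndarray:
        return np.array([self.kappa_x, self.kappa_y])

    @property
    def kt(self) -> float:
        """Thermal energy k_B*T, pN·µm."""
        return KB * self.temperature


@dataclass
class BeadGeometry:
    """Spherical bead in a viscous medium (Stokes regime).

    ``drag`` and ``diffusion`` are derived quantities and always satisfy the
    Stokes–Einstein identities gamma = 6*pi*eta*a and D = k_B*T/gamma.
    """

    radius: float
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError("bead radius must be positive")
        if self.viscosity <= 0:
            raise InvalidParameterError("viscosity must be positive")

    @property
    def drag(self) -> float:
        """Translational Stokes drag coefficient gamma, pN·s/µm."""
        return 6.0 * math.pi * self.viscosity * self.radius

    def diffusion(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        """Einstein diffusivity k_B*T/gamma, µm²/s."""
        if temperature <= 0:
            raise InvalidParameterError("temperature must be positive")
        return KB * temperature / self.drag


# ---------------------------------------------------------------------------
# Behavioral schedule
# ---------------------------------------------------------------------------

#: States the trapped-bead simulator understands.
TRAPPED_STATES = ("gyration", "pilus_cycle", "long_axis_rotation", "brownian")
#: States the pole-track simulator understands.
POLE_STATES = ("bending", "long_axis_rotation", "released")
#: States of the free swimmer.
SWIM_STATES = ("swim_push", "swim_pull")

ALL_STATES = tuple(sorted(set(TRAPPED_STATES + POLE_STATES + SWIM_STATES)))


@dataclass
class Segment:
    """One contiguous behavioral state interval with state-specific params."""

    state: str
    start: float
    duration: float
    params: dict = field(default_factory=dict)

    @property
    def end(self) -> float:
        return self.start + self.duration


class BehaviorSchedule:
    """Ordered, contiguous, non-overlapping behavioral states starting at 0."""

    def __init__(self, segments: Iterable[Segment]):
        segs = list(segments)
        if not segs:
            raise InvalidParameterError("schedule must contain >= 1 segment")
        t = 0.0
        for seg in segs:
            if seg.state not in ALL_STATES:
                raise InvalidParameterError(f"unknown state {seg.state!r}")
            if seg.duration <= 0:
                raise InvalidParameterError("segment durations must be positive")
            if abs(seg.start - t) > 1e-9:
                raise InvalidParameterError(
                    "segments must be contiguous and start at 0"
                )
            t = seg.end
        self.segments = segs

    @classmethod
    def from_durations(cls, states_durations: Iterable[tuple], **common) -> "BehaviorSchedule":
        """Build a schedule from ``(state, duration[, params])`` tuples."""
        segs, t = [], 0.0
        for item in states_durations:
            state, duration = item[0], item[1]
            params = dict(item[2]) if len(item) > 2 else {}
            params.update(common)
            segs.append(Segment(state, t, duration, params))
            t += duration
        return cls(segs)

    @property
    def total_time(self) -> float:
        return self.segments[-1].end

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class DrivingParams:
    """Flagellar driving of the trapped bead.

    ``rot_force`` is the tangential force magnitude (pN) w.r.t. the
    instantaneous radius from the trap centre; ``trans_force`` the radial
    (outward) force.  If ``rot_force`` is None it is derived from
    ``gyration_freq`` through the overdamped drag balance
    rot_force = 2*pi*f*gamma*trans_force/kappa.
    """

    rot_force: float | None = 0.3
    trans_force: float = 1.2
    gyration_freq: float | None = None
    gyration_direction: str = "CCW"
    slow_factor: float = 0.5  # rot_force multiplier in the long-axis-rotation stage

    def __post_init__(self) -> None:
        if self.gyration_direction not in ("CW", "CCW"):
            raise InvalidParameterError("gyration_direction must be CW or CCW")
        if self.rot_force is None and self.gyration_freq is None:
            raise InvalidParameterError("need rot_force or gyration_freq")
        for v in (self.rot_force, self.trans_force, self.gyration_freq):
            if v is not None and v < 0:
                raise InvalidParameterError("forces and frequencies must be >= 0")
        if not 0 < self.slow_factor <= 1:
            raise InvalidParameterError("slow_factor must be in (0, 1]")


@dataclass
class PilusParams:
    """Kinematic type IV pilus attachment-cycle parameters."""

    retract_speed: float = 0.1       # µm/s
    hold_displacement: float = 0.5   # µm added along the anchor direction
    release_speed_factor: float = 10.0
    cycle_duration_mean: float = 12.9
    cycle_duration_sd: float = 11.4
    intercycle_mean: float = 10.5
    intercycle_sd: float = 5.1
    jitter: float = 0.01             # µm, localization-scale jitter while tethered

    def __post_init__(self) -> None:
        if self.retract_speed < 0 or self.hold_displacement < 0:
            raise InvalidParameterError("pilus kinematics must be >= 0")
        if self.release_speed_factor < 1:
            raise InvalidParameterError("release_speed_factor must be >= 1")


@dataclass
class SwimParams:
    """Run-reverse swimming of the free bacteria-on-a-bead."""

    v_push: float = 12.8   # µm/s (mean; per-sequence draws optional)
    v_pull: float = 17.7
    v_push_sd: float = 0.0
    v_pull_sd: float = 0.0
    tau_push: float = 2.2  # s, exponential mean
    tau_pull: float = 1.2
    rotational_diffusion: float = 0.1  # rad²/s
    speed_floor: float = 2.0           # µm/s, lower truncation of speed draws

    def __post_init__(self) -> None:
        if self.tau_push <= 0 or self.tau_pull <= 0:
            raise InvalidParameterError("run duration means must be positive")
        for v in (self.v_push, self.v_pull, self.v_push_sd, self.v_pull_sd,
                  self.rotational_diffusion):
            if v < 0:
                raise InvalidParameterError("speeds and diffusivities must be >= 0")


@dataclass
class PoleParams:
    """Flagellated-pole motion of a surface-attached predivisional cell."""

    freq_ccw_mean: float = 20.4
    freq_ccw_sd: float = 15.0
    freq_cw_mean: float = 29.9
    freq_cw_sd: float = 25.6
    freq_lower: float = 1.0       # Hz, lower truncation of frequency draws
    amplitude: float = 0.25       # µm, long-axis rotation radius of the pole
    bend_amplitude: float = 2.0   # µm
    bend_freq: float = 0.2        # Hz, sub-Hz bending oscillation
    noise: float = 0.025          # µm, localization noise (amplitude/SNR)

    def __post_init__(self) -> None:
        for v in (self.freq_ccw_mean, self.freq_cw_mean, self.amplitude,
                  self.bend_amplitude, self.noise):
            if v < 0:
                raise InvalidParameterError("pole parameters must be >= 0")


@dataclass
class SimulationConfig:
    """Everything a simulator run needs; one seed -> bit-identical output."""

    trap: TrapModel = field(default_factory=lambda: TrapModel(2.0, 2.0))
    bead: BeadGeometry = field(default_factory=lambda: BeadGeometry(1.5))
    frame_rate: float = 50.0
    total_time: float | None = None
    integration_step: float | None = None  # default: min(1 ms, 1/(10*frame_rate))
    seed: int = 0
    driving: DrivingParams = field(default_factory=DrivingParams)
    pilus: PilusParams = field(default_factory=PilusParams)
    swim: SwimParams = field(default_factory=SwimParams)
    pole: PoleParams = field(default_factory=PoleParams)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.integration_step is not None:
            if self.integration_step <= 0:
                raise InvalidParameterError("integration_step must be positive")
            if self.integration_step > 1.0 / (2.0 * self.frame_rate):
                raise InvalidParameterError(
                    "integration_step must be <= 1/(2*frame_rate)"
                )

    @property
    def step(self) -> float:
        if self.integration_step is not None:
            return self.integration_step
        return min(1e-3, 1.0 / (10.0 * self.frame_rate))


# ---------------------------------------------------------------------------
# Trajectories and event tables
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Uniformly sampled 2-D position time series.

    ``aux`` carries non-serialized side information (ground-truth body axis,
    planted parameters); it is written to the JSON sidecar only where entries
    are plain scalars/lists.
    """

    times: np.ndarray
    positions: np.ndarray
    frame_rate: float
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise InvalidParameterError("trajectory needs >= 2 samples")
        if self.positions.shape != (len(self.times), 2):
            raise InvalidParameterError("positions must be (n, 2)")
        dt = np.diff(self.times)
        if np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-9):
            raise InvalidParameterError("sampling must be uniform at frame_rate")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame(
            {"t_s": self.times, "x_um": self.positions[:, 0],
             "y_um": self.positions[:, 1]}
        ).to_csv(path, index=False)
        if sidecar:
            meta = {"frame_rate_hz": self.frame_rate}
            for k, v in self.aux.items():
                if isinstance(v, (int, float, str, bool)):
                    meta[k] = v
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float | None = None) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        if frame_rate is None:
            sidecar = path.with_suffix(".json")
            if sidecar.exists():
                frame_rate = json.loads(sidecar.read_text())["frame_rate_hz"]
            else:
                frame_rate = 1.0 / float(np.median(np.diff(df["t_s"])))
        return cls(df["t_s"].to_numpy(),
                   df[["x_um", "y_um"]].to_numpy(), frame_rate)


class PoleTrack(Trajectory):
    """Position of the flagellated pole of a surface-attached cell."""


@dataclass
class Event:
    """One behavioral interval; ground truth or inference output."""

    state: str
    start: float
    end: float
    attrs: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start


class EventTable:
    """Sorted, non-overlapping behavioral intervals of one track."""

    def __init__(self, events: Iterable[Event]):
        evs = sorted(events, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end - 1e-9:
                raise InvalidParameterError("events must not overlap")
        for e in evs:
            if e.end <= e.start:
                raise InvalidParameterError("events must have positive duration")
        self.events = evs

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def select(self, *states: str) -> list[Event]:
        return [e for e in self.events if e.state in states]

    def state_time(self, *states: str) -> float:
        return sum(e.duration for e in self.select(*states))

    def state_at(self, t: float) -> str | None:
        for e in self.events:
            if e.start - 1e-9 <= t < e.end - 1e-9 or (
                e is self.events[-1] and abs(t - e.end) <= 1e-9
            ):
                return e.state
        return None

    def frame_labels(self, times: np.ndarray) -> np.ndarray:
        """State label per sample time (object array of str or None)."""
        labels = np.empty(len(times), dtype=object)
        starts = np.array([e.start for e in self.events])
        idx = np.searchsorted(starts, np.asarray(times) + 1e-9) - 1
        for i, j in enumerate(idx):
            if j >= 0 and times[i] < self.events[j].end + 1e-9:
                labels[i] = self.events[j].state
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"state": e.state, "start_s": e.start, "end_s": e.end,
              "attributes": json.dumps(e.attrs)} for e in self.events]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(
            Event(r["state"], r["start_s"], r["end_s"],
                  json.loads(r["attributes"]) if isinstance(r.get("attributes"), str) else {})
            for _, r in df.iterrows()
        )


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Synthetic bright-field-like image stack (frame, row, col)."""

    frames: np.ndarray
    pixel_size: float  # µm per pixel
    frame_rate: float
    bit_depth: int = 16
    origin_um: tuple[float, float] = (0.0, 0.0)  # µm position of pixel (0, 0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidParameterError("stack must be (n_frames, rows, cols)")
        if self.frames.max(initial=0) > 2 ** self.bit_depth - 1:
            raise InvalidParameterError("intensities exceed bit depth")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.frames.astype(np.uint16 if self.bit_depth > 8 else np.uint8),
            imagej=True,
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "finterval": 1.0 / self.frame_rate},
        )

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float,
                  frame_rate: float, bit_depth: int = 16) -> "ImageStack":
        import tifffile

        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames, pixel_size, frame_rate, bit_depth)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class Aggregate:
    """mean ± SD over n observations of one named quantity."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParameterError("aggregate needs n >= 1")
        if self.sd < 0:
            raise InvalidParameterError("SD must be >= 0")

    @classmethod
    def of(cls, values: Iterable[float]) -> "Aggregate":
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise InvalidParameterError("no observations")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(float(arr.mean()), sd, int(arr.size))


class SummaryStats(dict):
    """Named scalar aggregates; missing categories are absent, never zero."""

    def add(self, name: str, values: Iterable[float]) -> None:
        vals = list(values)
        if vals:
            self[name] = Aggregate.of(vals)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: asdict(v) if isinstance(v, Aggregate) else v
                   for k, v in self.items()}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Package defaults fixture
# ---------------------------------------------------------------------------


def assay_defaults() -> dict[str, Any]:
    """Load the packaged defaults fixture (reference assay means/SDs/ranges)."""
    from importlib import resources

    with resources.files("beadcycle").joinpath("assay_defaults.json").open() as fh:
        return json.load(fh)


def child_rng(master_seed: int, *key: Any) -> np.random.Generator:
    """Independent, reproducible stream for (master seed, track id, ...).

    String key components are hashed with CRC32 (stable across processes,
    unlike built-in ``hash``).
    """
    import zlib

    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=tuple(
            zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
            for k in key
        ),
    ))
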