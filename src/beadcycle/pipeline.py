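"""End-to-end recovery experiments and the reporting pipeline.

Each experiment plants known behavioral parameters through the synthetic
generator, runs the inference stages (segmentation, cycle extraction, swim
classification, rotation analysis, force inference), and reports the
recovered quantity next to the planted per-run sample value and the
packaged default (population) value.  Stochastic recovery is judged
estimator-to-planted-sample (tight, same realization) while
planted-to-default is a parameterization identity that holds by
construction of the moment-matched generators.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .calibration import stiffness_equipartition, stiffness_psd
from .forces import displacement_force, summarize_forces
from .models import (
    BeadGeometry,
    BehaviorSchedule,
    DrivingParams,
    PoleParams,
    SimulationConfig,
    SummaryStats,
    SwimParams,
    TrapModel,
    child_rng,
    assay_defaults,
)
from .segmentation import (
    SegmentationThresholds,
    classify_states,
    compute_features,
    extract_pilus_cycles,
    summarize_events,
)
from .swim import classify_swim_sequences, rotation_frequency, swim_statistics

__all__ = [
    "default_trapped_config",
    "default_swimmer_config",
    "default_pole_config",
    "swim_speed_recovery",
    "swim_duration_recovery",
    "pilus_cycle_recovery",
    "pole_frequency_recovery",
    "activity_recovery",
    "force_recovery",
    "calibration_recovery",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Study-condition configurations
# ---------------------------------------------------------------------------


def default_trapped_config(seed: int = 0, defaults: dict | None = None
                           ) -> SimulationConfig:
    """Trapped 3 µm bead at the packaged assay conditions."""
    d = defaults or assay_defaults()
    trap = TrapModel(d["trap"]["kappa_x_pN_per_um"],
                     d["trap"]["kappa_y_pN_per_um"],
                     temperature=d["temperature_K"])
    bead = BeadGeometry(d["bead"]["radius_trapped_um"],
                        d["viscosity_pNs_per_um2"])
    driving = DrivingParams(rot_force=d["driving"]["rot_force_pN"],
                            trans_force=d["driving"]["trans_force_pN"],
                            gyration_direction=d["driving"]["gyration_direction"],
                            slow_factor=d["driving"]["long_axis_slow_factor"])
    return SimulationConfig(trap=trap, bead=bead,
                            frame_rate=d["frame_rate_Hz"]["trapped"],
                            seed=seed, driving=driving)


def default_swimmer_config(seed: int = 0, defaults: dict | None = None,
                           draw_speeds: bool = True) -> SimulationConfig:
    """Free-swimming bacteria-on-a-bead (1 µm bead, quasi-2D chamber).

    The positional noise uses an effective assembly radius of 1.5 µm (bead
    plus cell body), not the bare 1 µm bead.
    """
    d = defaults or assay_defaults()
    sw = d["swim"]
    swim = SwimParams(
        v_push=sw["v_push_um_per_s"]["mean"],
        v_pull=sw["v_pull_um_per_s"]["mean"],
        v_push_sd=sw["v_push_um_per_s"]["sd"] if draw_speeds else 0.0,
        v_pull_sd=sw["v_pull_um_per_s"]["sd"] if draw_speeds else 0.0,
        tau_push=sw["tau_push_s"], tau_pull=sw["tau_pull_s"],
        rotational_diffusion=sw["rotational_diffusion_rad2_per_s"],
        speed_floor=sw["speed_floor_um_per_s"])
    return SimulationConfig(
        trap=TrapModel(1.0, 1.0, temperature=d["temperature_K"]),
        bead=BeadGeometry(1.5, d["viscosity_pNs_per_um2"]),
        frame_rate=d["frame_rate_Hz"]["swimmer"], seed=seed, swim=swim)


def default_pole_config(seed: int = 0, defaults: dict | None = None
                        ) -> SimulationConfig:
    """Surface-attached predivisional cell pole, high-speed recording."""
    d = defaults or assay_defaults()
    pole = PoleParams(
        freq_ccw_mean=d["pole_frequency_Hz"]["ccw"]["mean"],
        freq_ccw_sd=d["pole_frequency_Hz"]["ccw"]["sd"],
        freq_cw_mean=d["pole_frequency_Hz"]["cw"]["mean"],
        freq_cw_sd=d["pole_frequency_Hz"]["cw"]["sd"])
    return SimulationConfig(
        trap=TrapModel(1.0, 1.0, temperature=d["temperature_K"]),
        bead=BeadGeometry(0.5, d["viscosity_pNs_per_um2"]),
        frame_rate=d["frame_rate_Hz"]["pole"], seed=seed, pole=pole)


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def swim_speed_recovery(seed: int, n_per_direction: int = 300,
                        defaults: dict | None = None) -> dict:
    """Plant per-sequence push/pull speeds, recover their means.

    Speeds are drawn per sequence from the moment-matched truncated-normal
    speed distributions; the classifier works from the ground-truth body
    axis.  Returns recovered and planted-sample mean speeds per direction.
    """
    cfg = default_swimmer_config(seed, defaults)
    rng = child_rng(seed, 11)
    traj, events = synthetic.simulate_free_swimmer(
        cfg, rng=rng, n_sequences=2 * n_per_direction)
    seqs = classify_swim_sequences(traj, speed_floor=cfg.swim.speed_floor)
    stats = swim_statistics(seqs)
    planted_push = [e.attrs["speed_um_s"] for e in events.select("swim_push")]
    planted_pull = [e.attrs["speed_um_s"] for e in events.select("swim_pull")]
    return {
        "recovered_push_speed": stats["push_speed_um_s"].mean,
        "recovered_pull_speed": stats["pull_speed_um_s"].mean,
        "planted_push_speed": float(np.mean(planted_push)),
        "planted_pull_speed": float(np.mean(planted_pull)),
        "n_push": stats["push_speed_um_s"].n,
        "n_pull": stats["pull_speed_um_s"].n,
    }


def swim_duration_recovery(seed: int, n_per_direction: int = 500,
                           defaults: dict | None = None) -> dict:
    """Plant exponential push/pull run durations, recover their means."""
    cfg = default_swimmer_config(seed, defaults, draw_speeds=False)
    rng = child_rng(seed, 13)
    traj, events = synthetic.simulate_free_swimmer(
        cfg, rng=rng, n_sequences=2 * n_per_direction)
    seqs = classify_swim_sequences(traj, speed_floor=cfg.swim.speed_floor)
    stats = swim_statistics(seqs)
    planted_push = [e.duration for e in events.select("swim_push")]
    planted_pull = [e.duration for e in events.select("swim_pull")]
    return {
        "recovered_push_duration": stats["push_duration_s"].mean,
        "recovered_pull_duration": stats["pull_duration_s"].mean,
        "planted_push_duration": float(np.mean(planted_push)),
        "planted_pull_duration": float(np.mean(planted_pull)),
        "time_fraction_push": stats["time_fraction_push"],
        "n_push": stats["push_duration_s"].n,
        "n_pull": stats["pull_duration_s"].n,
    }


def _segment_trapped(traj, cfg, split_long_axis=False):
    thr = SegmentationThresholds.from_trap(cfg.trap)
    feats = compute_features(traj, cfg.trap.center)
    events = classify_states(feats, thr, split_long_axis=split_long_axis)
    return events, thr


def pilus_cycle_recovery(seed: int, n_tracks: int = 20,
                         cycles_per_track: int = 15, flagellum: bool = True,
                         defaults: dict | None = None) -> dict:
    """Plant pilus attachment cycles, recover durations and inter-cycle gaps.

    With the flagellum present the bead gyrates between cycles; in the
    flagellum-less condition (hook-deletion mimic) inter-cycle motion is
    Brownian only.  Cycle durations and gaps are drawn from the
    moment-matched packaged distributions for the matching condition.
    """
    d = defaults or assay_defaults()
    dists = synthetic.assay_distributions(d)
    key = "pilus_cycle" if flagellum else "pilus_cycle_no_flagellum"
    ikey = "pilus_intercycle" if flagellum else "pilus_intercycle_no_flagellum"
    planted_cycles, planted_gaps = [], []
    recovered_cycles, recovered_gaps = [], []
    for k in range(n_tracks):
        rng = child_rng(seed, 29, k)
        cfg = default_trapped_config(seed, d)
        schedule = synthetic.pilus_interleaved_schedule(
            rng, cycles_per_track, dists[key], dists[ikey],
            flagellum=flagellum)
        traj, truth = synthetic.simulate_trapped_bead(cfg, schedule, rng=rng)
        planted_cycles += [e.attrs["cycle_duration_s"]
                           for e in truth.select("pilus_cycle")]
        tp = [e for e in truth.select("pilus_cycle")]
        planted_gaps += [b.start - a.end for a, b in zip(tp, tp[1:])]
        events, thr = _segment_trapped(traj, cfg)
        cycles = extract_pilus_cycles(events, traj, cfg.trap.center, thr)
        cycles = [c for c in cycles if c.complete]
        recovered_cycles += [c.duration for c in cycles]
        recovered_gaps += [b.attach - a.release_end
                           for a, b in zip(cycles, cycles[1:])
                           if b.attach > a.release_end]
    return {
        "recovered_cycle_duration": float(np.mean(recovered_cycles)),
        "planted_cycle_duration": float(np.mean(planted_cycles)),
        "recovered_intercycle": float(np.mean(recovered_gaps))
        if recovered_gaps else float("nan"),
        "planted_intercycle": float(np.mean(planted_gaps)),
        "n_cycles": len(recovered_cycles),
        "n_gaps": len(recovered_gaps),
    }


def pole_frequency_recovery(seed: int, n_cells: int = 300,
                            defaults: dict | None = None) -> dict:
    """Plant per-cell CW/CCW rotation frequencies, recover pooled means."""
    d = defaults or assay_defaults()
    dists = synthetic.assay_distributions(d)
    planted = {"CCW": [], "CW": []}
    recovered = {"CCW": [], "CW": []}
    for k in range(n_cells):
        rng = child_rng(seed, 31, k)
        cfg = default_pole_config(seed, d)
        f_ccw = float(dists["freq_ccw"].rvs(random_state=rng))
        f_cw = float(dists["freq_cw"].rvs(random_state=rng))
        planted["CCW"].append(f_ccw)
        planted["CW"].append(f_cw)
        schedule = synthetic.pole_rotation_schedule(rng, f_ccw, f_cw)
        track, _ = synthetic.simulate_pole_track(cfg, schedule, rng=rng)
        ests = rotation_frequency(track)
        for direction in ("CCW", "CW"):
            fs = [e.frequency for e in ests if e.direction == direction]
            if fs:
                recovered[direction].append(float(np.mean(fs)))
    return {
        "recovered_ccw_freq": float(np.mean(recovered["CCW"])),
        "recovered_cw_freq": float(np.mean(recovered["CW"])),
        "planted_ccw_freq": float(np.mean(planted["CCW"])),
        "planted_cw_freq": float(np.mean(planted["CW"])),
        "n_cells": n_cells,
        "n_ccw": len(recovered["CCW"]),
        "n_cw": len(recovered["CW"]),
    }


def activity_recovery(seed: int, n_tracks: int = 60,
                      include_rotation_stage: bool = True,
                      defaults: dict | None = None) -> dict:
    """Plant flagellar-activity lifetimes, recover onset-to-separation spans.

    Each track is Brownian, then gyrates for the drawn activity duration
    (its tail slowed into the long-axis-rotation stage), then returns to
    Brownian after separation.  Onset and separation are detected by the
    rule cascade.
    """
    d = defaults or assay_defaults()
    dists = synthetic.assay_distributions(d)
    planted_act, planted_rot = [], []
    recovered_act, recovered_rot = [], []
    for k in range(n_tracks):
        rng = child_rng(seed, 37, k)
        cfg = default_trapped_config(seed, d)
        schedule, planted = synthetic.activity_schedule(
            rng, dists["activity"],
            dists["rotation_stage"] if include_rotation_stage else None)
        traj, _ = synthetic.simulate_trapped_bead(cfg, schedule, rng=rng)
        planted_act.append(planted["activity_s"])
        if "rotation_stage_s" in planted:
            planted_rot.append(planted["rotation_stage_s"])
        events, _ = _segment_trapped(traj, cfg,
                                     split_long_axis=include_rotation_stage)
        stats = summarize_events(events)
        if "activity_duration_s" in stats:
            recovered_act.append(stats["activity_duration_s"].mean)
        if "rotation_stage_total_s" in stats:
            recovered_rot.append(stats["rotation_stage_total_s"].mean)
    out = {
        "recovered_activity": float(np.mean(recovered_act)),
        "planted_activity": float(np.mean(planted_act)),
        "n_tracks": n_tracks,
        "n_recovered": len(recovered_act),
    }
    if planted_rot:
        out["recovered_rotation_stage"] = float(np.mean(recovered_rot))
        out["planted_rotation_stage"] = float(np.mean(planted_rot))
    return out


def force_recovery(seed: int, duration: float = 30.0,
                   defaults: dict | None = None) -> dict:
    """Plant gyration driving forces, recover F_rot and F_trans_max."""
    d = defaults or assay_defaults()
    cfg = default_trapped_config(seed, d)
    rng = child_rng(seed, 41)
    schedule = BehaviorSchedule.from_durations([("gyration", duration)])
    traj, truth = synthetic.simulate_trapped_bead(cfg, schedule, rng=rng)
    fs = displacement_force(traj, cfg.trap)
    summary = summarize_forces(fs, cfg.bead, truth,
                               kappa=cfg.trap.kappa)
    return {
        "recovered_f_rot": summary.f_rot,
        "planted_f_rot": synthetic.derived_rot_force(cfg),
        "recovered_f_trans_max": summary.f_trans_max,
        "planted_f_trans_max": cfg.driving.trans_force,
    }


def calibration_recovery(seed: int, n_frames: int = 100_000,
                         frame_rate: float = 20.0, kappa: float = 0.05,
                         defaults: dict | None = None) -> dict:
    """Plant a trap stiffness, recover it by equipartition and PSD."""
    d = defaults or assay_defaults()
    trap = TrapModel(kappa, kappa, temperature=d["temperature_K"])
    bead = BeadGeometry(d["bead"]["radius_trapped_um"],
                        d["viscosity_pNs_per_um2"])
    cfg = SimulationConfig(trap=trap, bead=bead, frame_rate=frame_rate,
                           seed=seed)
    rng = child_rng(seed, 43)
    schedule = BehaviorSchedule.from_durations(
        [("brownian", n_frames / frame_rate)])
    traj, _ = synthetic.simulate_trapped_bead(cfg, schedule, rng=rng)
    eq = stiffness_equipartition(traj, trap.temperature, n_boot=200,
                                 rng=child_rng(seed, 44))
    psd = stiffness_psd(traj, trap.temperature, bead.drag)
    return {
        "planted_kappa": kappa,
        "kappa_equipartition": float(np.mean(eq.kappa)),
        "kappa_psd": float(np.mean(psd.kappa)),
        "n_frames": n_frames,
    }


# ---------------------------------------------------------------------------
# Report pipeline
# ---------------------------------------------------------------------------


def run_pipeline(out_dir: str | Path, seed: int = 1, scale: float = 1.0,
                 defaults: dict | None = None) -> pd.DataFrame:
    """Run every recovery experiment and write the report bundle.

    ``scale`` multiplies the experiment sample sizes (0.2 for a quick look).
    Writes per-quantity recovery rows (planted sample vs. recovered vs.
    packaged default) to ``recovery_table.csv`` plus a JSON summary; the
    run is deterministic for a fixed seed.
    """
    d = defaults or assay_defaults()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def n(x: int) -> int:
        return max(2, int(round(x * scale)))

    sp = swim_speed_recovery(seed, n_per_direction=n(300), defaults=d)
    du = swim_duration_recovery(seed, n_per_direction=n(500), defaults=d)
    pw = pilus_cycle_recovery(seed, n_tracks=n(20), flagellum=True, defaults=d)
    pn = pilus_cycle_recovery(seed, n_tracks=n(20), flagellum=False,
                              defaults=d)
    po = pole_frequency_recovery(seed, n_cells=n(300), defaults=d)
    ac = activity_recovery(seed, n_tracks=n(60), defaults=d)
    fo = force_recovery(seed, defaults=d)
    ca = calibration_recovery(seed, n_frames=n(100_000), defaults=d)

    sw = d["swim"]
    rows = [
        ("push_speed_um_s", sp["planted_push_speed"],
         sp["recovered_push_speed"], sw["v_push_um_per_s"]["mean"], sp["n_push"]),
        ("pull_speed_um_s", sp["planted_pull_speed"],
         sp["recovered_pull_speed"], sw["v_pull_um_per_s"]["mean"], sp["n_pull"]),
        ("push_duration_s", du["planted_push_duration"],
         du["recovered_push_duration"], sw["tau_push_s"], du["n_push"]),
        ("pull_duration_s", du["planted_pull_duration"],
         du["recovered_pull_duration"], sw["tau_pull_s"], du["n_pull"]),
        ("pilus_cycle_s", pw["planted_cycle_duration"],
         pw["recovered_cycle_duration"], d["pilus"]["cycle_s"]["mean"],
         pw["n_cycles"]),
        ("pilus_intercycle_s", pw["planted_intercycle"],
         pw["recovered_intercycle"], d["pilus"]["intercycle_s"]["mean"],
         pw["n_gaps"]),
        ("pilus_cycle_no_flagellum_s", pn["planted_cycle_duration"],
         pn["recovered_cycle_duration"],
         d["pilus"]["cycle_no_flagellum_s"]["mean"], pn["n_cycles"]),
        ("pole_freq_ccw_hz", po["planted_ccw_freq"], po["recovered_ccw_freq"],
         d["pole_frequency_Hz"]["ccw"]["mean"], po["n_ccw"]),
        ("pole_freq_cw_hz", po["planted_cw_freq"], po["recovered_cw_freq"],
         d["pole_frequency_Hz"]["cw"]["mean"], po["n_cw"]),
        ("activity_s", ac["planted_activity"], ac["recovered_activity"],
         d["activity_s"]["mean"], ac["n_recovered"]),
        ("rotation_stage_s", ac["planted_rotation_stage"],
         ac["recovered_rotation_stage"], d["rotation_stage_s"]["mean"],
         ac["n_recovered"]),
        ("f_rot_pN", fo["planted_f_rot"], fo["recovered_f_rot"],
         d["driving"]["rot_force_pN"], 1),
        ("f_trans_max_pN", fo["planted_f_trans_max"],
         fo["recovered_f_trans_max"], d["driving"]["trans_force_pN"], 1),
        ("kappa_pN_um", ca["planted_kappa"], ca["kappa_equipartition"],
         ca["planted_kappa"], ca["n_frames"]),
    ]
    table = pd.DataFrame(rows, columns=["quantity", "planted_sample",
                                        "recovered", "default_value", "n"])
    table.to_csv(out / "recovery_table.csv", index=False)
    summary = SummaryStats()
    for _, r in table.iterrows():
        summary[r["quantity"]] = {
            "planted_sample": r["planted_sample"],
            "recovered": r["recovered"],
            "default_value": r["default_value"],
            "n": int(r["n"]),
        }
    (out / "summary.json").write_text(summary.to_json())
    (out / "run_config.json").write_text(json.dumps(
        {"seed": seed, "scale": scale}, indent=1))
    return table
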