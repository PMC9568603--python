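{
  "temperature_K": 303.15,
  "viscosity_pNs_per_um2": 0.001,
  "trap": {
    "kappa_x_pN_per_um": 2.0,
    "kappa_y_pN_per_um": 2.0
  },
  "bead": {
    "radius_trapped_um": 1.5,
    "radius_swimmer_um": 0.5
  },
  "frame_rate_Hz": {
    "swimmer": 20.0,
    "trapped": 50.0,
    "pole": 200.0
  },
  "driving": {
    "rot_force_pN": 0.3,
    "trans_force_pN": 1.2,
    "gyration_direction": "CCW",
    "long_axis_slow_factor": 0.5
  },
  "swim": {
    "v_push_um_per_s": {"mean": 12.8, "sd": 6.1},
    "v_pull_um_per_s": {"mean": 17.7, "sd": 6.5},
    "tau_push_s": 2.2,
    "tau_pull_s": 1.2,
    "speed_floor_um_per_s": 2.0,
    "rotational_diffusion_rad2_per_s": 0.1
  },
  "activity_s": {"mean": 99.8, "sd": 57.3, "lower": 40.0, "upper": 180.0},
  "rotation_stage_s": {"mean": 10.3, "sd": 7.6, "lower": 2.0, "upper": 17.0},
  "bending_s": {"mean": 120.0, "sd": 60.0, "lower": 10.0, "upper": 420.0},
  "pole_frequency_Hz": {
    "ccw": {"mean": 20.4, "sd": 15.0, "lower": 1.0, "upper": 50.0},
    "cw": {"mean": 29.9, "sd": 25.6, "lower": 1.0, "upper": 50.0}
  },
  "pilus": {
    "retract_speed_um_per_s": 0.1,
    "hold_displacement_um": 0.5,
    "release_speed_factor": 10.0,
    "cycle_s": {"mean": 12.9, "sd": 11.4, "lower": 2.0},
    "intercycle_s": {"mean": 10.5, "sd": 5.1, "lower": 0.5},
    "cycle_no_flagellum_s": {"mean": 19.9, "sd": 16.8, "lower": 2.0},
    "intercycle_no_flagellum_s": {"mean": 23.4, "sd": 22.0, "lower": 0.5}
  },
  "displacement_share_s": {
    "pili": {"mean": 100.6, "sd": 60.8},
    "flagellum": {"mean": 230.9, "sd": 207.4}
  },
  "time_fraction": {"pili": 0.3, "flagellum": 0.7}
}
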