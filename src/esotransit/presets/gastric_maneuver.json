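{
  "posture": "gastric_maneuver",
  "transit_duration_s": 6.0,
  "path_length_cm": 35.0,
  "oral_peak_cmH2O": -141.0,
  "rear_contraction_peak_cmH2O": 85.0,
  "front_contraction_peak_cmH2O": 40.0,
  "front_dip_cmH2O": 0.0,
  "after_contraction_cmH2O": 0.0,
  "peak_velocity_cm_s": 0.0,
  "cardiac_amplitude_m_s2": 0.0,
  "cardiac_freq_hz": 1.0,
  "noise": {
    "accel_sigma": 0.05,
    "gyro_sigma": 0.005,
    "mag_sigma": 0.5,
    "pressure_sigma": 1.0,
    "accel_bias": [0.0, 0.0, 0.0],
    "gyro_bias": [0.0, 0.0, 0.0]
  },
  "maneuvers": [
    ["leg_raise", 30.0, 50.0, 50.0],
    ["deep_inspiration", 70.0, 90.0, 15.0]
  ],
  "sample_rate_hz": 50.0,
  "duration_s": 110.0,
  "seed": 0,
  "yaw_deg": 0.0,
  "device_length_cm": 4.2,
  "subject_label": "synthetic-gastric"
}
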