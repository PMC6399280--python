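{
  "_meta": {
    "description": "Default typist profiles for the four group x language cells. Mechanism mixes, IKI medians and error slowing are calibration constants chosen by scripts/calibrate_profiles.py so that cohort means measured by the full align-classify-filter-summarize pipeline reproduce the published per-group motor rates, habit rates and mean interkey intervals.",
    "calibrated": true,
    "verification": {
      "english-control": {
        "motor": 0.00031,
        "habit": 0.00156,
        "iki_c": -0.00137,
        "iki_e": -0.0024
      },
      "english-patient": {
        "motor": 0.00266,
        "habit": 0.00178,
        "iki_c": -0.00085,
        "iki_e": -0.00187
      },
      "spanish-control": {
        "motor": -0.00031,
        "habit": 0.00834,
        "iki_c": -0.0005,
        "iki_e": -0.00038
      },
      "spanish-patient": {
        "motor": 0.00266,
        "habit": 0.00101,
        "iki_c": -0.00085,
        "iki_e": -0.00085
      }
    }
  },
  "english-control": {
    "group": "control",
    "language": "en",
    "iki_median_ms": 281.27,
    "iki_log_sd": 0.4,
    "iki_between_sd": 0.36,
    "error_slowing": 1.2732,
    "p_error": 0.04,
    "mechanism_mix": {
      "motor": 0.28805,
      "habit": 0.39199,
      "uniform": 0.3199600000000001
    },
    "mix_jitter_sd": 0.25,
    "speed_coupling": 0.5,
    "updrs_mean": 0.85
  },
  "english-patient": {
    "group": "patient",
    "language": "en",
    "iki_median_ms": 467.73,
    "iki_log_sd": 0.5,
    "iki_between_sd": 0.44,
    "error_slowing": 1.3832,
    "p_error": 0.05,
    "mechanism_mix": {
      "motor": 0.51743,
      "habit": 0.20116,
      "uniform": 0.28141000000000005
    },
    "mix_jitter_sd": 0.25,
    "speed_coupling": 0.5,
    "updrs_mean": 13.15
  },
  "spanish-control": {
    "group": "control",
    "language": "es",
    "iki_median_ms": 264.77,
    "iki_log_sd": 0.4,
    "iki_between_sd": 0.15,
    "error_slowing": 1.4079,
    "p_error": 0.04,
    "mechanism_mix": {
      "motor": 0.19719802801971978,
      "habit": 0.4583654163458365,
      "uniform": 0.34443655563444375
    },
    "mix_jitter_sd": 0.25,
    "speed_coupling": 0.5,
    "updrs_mean": 0.85
  },
  "spanish-patient": {
    "group": "patient",
    "language": "es",
    "iki_median_ms": 378.92,
    "iki_log_sd": 0.5,
    "iki_between_sd": 0.25,
    "error_slowing": 1.2837,
    "p_error": 0.05,
    "mechanism_mix": {
      "motor": 0.39962,
      "habit": 0.30318,
      "uniform": 0.2972
    },
    "mix_jitter_sd": 0.25,
    "speed_coupling": 0.5,
    "updrs_mean": 13.15
  }
}
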