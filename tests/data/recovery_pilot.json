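{
  "ddm": {
    "median_abs_error": {
      "delta_p": 0.03508,
      "s": 0.02002
    },
    "n_agents": 5,
    "n_datasets": 6,
    "n_trials": 100,
    "tolerance": {
      "delta_p": 0.07016,
      "s": 0.04005
    },
    "true": {
      "delta_p": 0.3,
      "s": 0.2
    }
  },
  "pilot_seed": 7777,
  "rl": {
    "median_abs_error": {
      "alpha": 0.03139,
      "beta": 0.01759,
      "sigma": 0.04382,
      "theta": 0.5577
    },
    "n_agents": 5,
    "n_groups": 12,
    "n_trials": 100,
    "tolerance": {
      "alpha": 0.06277,
      "beta": 0.03517,
      "sigma": 0.08763,
      "theta": 1.1154
    },
    "true": {
      "alpha": 0.3,
      "beta": 0.18,
      "sigma": 0.3,
      "theta": 1.5
    }
  }
}
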