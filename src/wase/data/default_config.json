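{
  "metadata": {
    "config_digest": "494386654112",
    "seed": 42,
    "substreams": {},
    "tool_version": "1.0.0"
  },
  "study": {
    "bootstrap_B": 2000,
    "cv_folds": 5,
    "hl_bins": 10,
    "n_weight_configs": 100,
    "population": {
      "age_bounds": [
        18.0,
        35.0
      ],
      "age_mean": 24.5,
      "age_sd": 5.2,
      "component_bounds": [
        [
          0.08,
          0.25
        ],
        [
          0.05,
          0.2
        ],
        [
          0.1,
          0.28
        ],
        [
          0.06,
          0.22
        ]
      ],
      "component_means": [
        0.15,
        0.08,
        0.12,
        0.1
      ],
      "component_sds": [
        0.04,
        0.03,
        0.05,
        0.04
      ],
      "correlation": [
        [
          1.0,
          0.45,
          0.35,
          0.55
        ],
        [
          0.45,
          1.0,
          0.25,
          0.65
        ],
        [
          0.35,
          0.25,
          1.0,
          0.3
        ],
        [
          0.55,
          0.65,
          0.3,
          1.0
        ]
      ],
      "n": 1000,
      "noise_cv": 0.05,
      "seed": 42,
      "sex_split": 0.5,
      "sport_props": [
        0.4,
        0.3,
        0.3
      ],
      "train_mean": 8.5,
      "train_sd": 3.1
    },
    "replicates": 1,
    "seed": 42,
    "sensitivity_delta": 0.05,
    "target_auc": 0.89,
    "target_prevalence": 0.2,
    "weights": {
      "ba": 0.15,
      "fv": 0.35,
      "ld": 0.22,
      "ta": 0.28
    }
  }
}
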