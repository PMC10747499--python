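{
  "rat_im": {
    "description": "Single-dose 2.5 mg IM long-acting cabotegravir in rats",
    "species": "rat",
    "route": "IM",
    "dose_mg": 2.5,
    "n_animals": 6,
    "cohort_weight_kg": {"mean": 0.241, "sd": 0.016},
    "metrics": {
      "auc_0_28": {"observed": 1268.1, "observed_sd": 290.3,
                   "predicted": 1431.1, "predicted_sd": 67.9,
                   "ratio": 1.13, "aafe": 1.13, "unit": "ug_day_ml",
                   "window_days": [0, 28]},
      "cmax": {"observed": 74.5, "observed_sd": 11.6,
               "predicted": 61.1, "predicted_sd": 2.1,
               "ratio": 0.82, "aafe": 1.22, "unit": "ug_ml"},
      "c28": {"observed": 14.5, "observed_sd": 1.5,
              "predicted": 20.0, "predicted_sd": 1.3,
              "ratio": 1.38, "aafe": 1.38, "unit": "ug_ml",
              "time_days": 28}
    },
    "profile_aafe": 1.10
  },
  "rat_map_single": {
    "description": "Single-dose 11.72 mg MAP cabotegravir in rats",
    "species": "rat",
    "route": "MAP",
    "dose_mg": 11.72,
    "n_animals": 6,
    "cohort_weight_kg": {"mean": 0.284, "sd": 0.010},
    "metrics": {
      "auc_0_28": {"observed": 291.1, "observed_sd": 23.4,
                   "predicted": 304.6, "predicted_sd": 7.6,
                   "ratio": 1.05, "aafe": 1.05, "unit": "ug_day_ml",
                   "window_days": [0, 28]},
      "cmax": {"observed": 18.1, "observed_sd": 2.3,
               "predicted": 20.7, "predicted_sd": 0.5,
               "ratio": 1.15, "aafe": 1.15, "unit": "ug_ml"},
      "c28": {"observed": 3.1, "observed_sd": 1.1,
              "predicted": 3.3, "predicted_sd": 0.09,
              "ratio": 1.06, "aafe": 1.06, "unit": "ug_ml",
              "time_days": 28}
    },
    "profile_aafe": 1.12
  },
  "rat_map_weekly": {
    "description": "Once-weekly 11.72 mg MAP cabotegravir in rats",
    "species": "rat",
    "route": "MAP",
    "dose_mg": 11.72,
    "interval_h": 168,
    "n_animals": 6,
    "cohort_weight_kg": {"mean": 0.198, "sd": 0.008},
    "sampling_note": "blood samples taken prior to dose four, 24 h post dose and 7 days post dose",
    "metrics": {
      "cmax_first": {"observed": 35.1, "observed_sd": 4.6,
                     "predicted": 28.7, "predicted_sd": 0.7,
                     "ratio": 0.82, "aafe": 1.22, "unit": "ug_ml"},
      "cmax_ss": {"observed": 60.3, "observed_sd": 10.7,
                  "predicted": 67.4, "predicted_sd": 1.8,
                  "ratio": 1.12, "aafe": 1.12, "unit": "ug_ml"},
      "c42": {"observed": 11.2, "observed_sd": 2.2,
              "predicted": 17.9, "predicted_sd": 0.6,
              "ratio": 1.60, "aafe": 1.60, "unit": "ug_ml",
              "time_days": 42}
    },
    "profile_aafe": 1.04
  },
  "human_im": {
    "description": "Single-dose 800 mg IM long-acting cabotegravir in HIV-negative adults",
    "species": "human",
    "route": "IM",
    "dose_mg": 800,
    "n_subjects": 6,
    "metrics": {
      "auc_0_w4": {"observed": 1497, "predicted": 1993.7,
                   "predicted_sd": 48.3, "ratio": 1.33, "aafe": 1.33,
                   "unit": "ug_h_ml", "window_weeks": [0, 4]},
      "auc_0_w12": {"observed": 3851, "predicted": 4792.7,
                    "predicted_sd": 65, "ratio": 1.24, "aafe": 1.24,
                    "unit": "ug_h_ml", "window_weeks": [0, 12]},
      "cmax": {"observed": 3.3, "predicted": 3.4, "predicted_sd": 0.06,
               "ratio": 1.02, "aafe": 1.02, "unit": "ug_ml"},
      "c_w4": {"observed": 2.0, "predicted": 2.8, "predicted_sd": 0.02,
               "ratio": 1.39, "aafe": 1.39, "unit": "ug_ml",
               "time_weeks": 4}
    },
    "profile_aafe": 1.23
  }
}
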