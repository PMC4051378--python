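{
  "algicidal_ratio_pct": {
    "regression": {"experimental_mean": 88.59, "experimental_sd": 3.46, "prediction": 103.00},
    "ga_ann": {"experimental_mean": 92.15, "experimental_sd": 1.12, "prediction": 90.50},
    "control": {"mean": 78.83, "sd": 2.76}
  },
  "dry_mycelial_weight_g_per_100mL": {
    "regression": {"experimental_mean": 0.2127, "experimental_sd": 0.0191, "prediction": 0.2598},
    "ga_ann": {"experimental_mean": 0.2165, "experimental_sd": 0.072, "prediction": 0.2283},
    "control": {"mean": 0.1279, "sd": 0.0116}
  },
  "_notes": [
    "Values transcribed verbatim from the published verification table.",
    "The GA-ANN dry-weight sd of 0.072 is anomalously large relative to its mean (0.2165) and to every other sd in the table; it is likely a misprint of 0.0072 but is stored as printed."
  ]
}
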