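{
  "schema_version": "1",
  "source": "2021 CKD-EPI race-free refit equations (creatinine; creatinine-cystatin C)",
  "equations": {
    "ckd_epi_2021_cr": {
      "inputs": ["scr", "age", "sex"],
      "level": 142.0,
      "kappa": {"female": 0.7, "male": 0.9},
      "alpha": {"female": -0.241, "male": -0.302},
      "scr_max_exponent": -1.200,
      "age_base": 0.9938,
      "female_multiplier": 1.012
    },
    "ckd_epi_2021_crcys": {
      "inputs": ["scr", "scys", "age", "sex"],
      "level": 135.0,
      "kappa": {"female": 0.7, "male": 0.9},
      "alpha": {"female": -0.219, "male": -0.144},
      "scr_max_exponent": -0.544,
      "cys_breakpoint": 0.8,
      "cys_min_exponent": -0.323,
      "cys_max_exponent": -0.778,
      "age_base": 0.9961,
      "female_multiplier": 0.963
    }
  }
}
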