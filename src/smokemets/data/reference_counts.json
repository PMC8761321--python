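{
  "comment": "Published group counts from the two source surveys (TNCHS discovery cohort, CHNS 2009 replication cohort); inputs for exact-arithmetic checks and crude-odds-ratio utilities.",
  "discovery": {
    "enrolled": 17219,
    "excluded_equivocal_mets": 1995,
    "excluded_missing_crucial_covariates": 2,
    "analyzed": 15222,
    "men": 7073,
    "women": 8149,
    "mets_positive": 3546,
    "mets_negative": 11676,
    "age_lt70": 9544,
    "age_ge70": 5678,
    "never_smokers": {"mets_positive": 3063, "all": 13739},
    "current_smokers": {"mets_positive": 455, "all": 1393},
    "former_smokers": {"mets_positive": 28, "all": 90},
    "components_by_mets_status": {
      "abdominal_obesity": {"mets_negative": 1534, "mets_positive": 1943},
      "high_blood_pressure": {"mets_negative": 3806, "mets_positive": 2729},
      "high_plasma_glucose": {"mets_negative": 2546, "mets_positive": 2478},
      "high_triglycerides": {"mets_negative": 2650, "mets_positive": 2438},
      "low_hdl": {"mets_negative": 1896, "mets_positive": 2373}
    }
  },
  "replication": {
    "excluded_equivocal_mets": 41,
    "excluded_invalid_smoking": 66,
    "analyzed": 8565,
    "men": 3976,
    "women": 4589,
    "mets_positive": 1559,
    "mets_negative": 7006,
    "never_smokers": {"mets_positive": 1047, "all": 5977},
    "current_smokers": {"mets_positive": 466, "all": 2401},
    "former_smokers": {"mets_positive": 46, "all": 187},
    "components_by_mets_status": {
      "abdominal_obesity": {"mets_negative": 1542, "mets_positive": 1283},
      "high_blood_pressure": {"mets_negative": 2346, "mets_positive": 1285},
      "high_plasma_glucose": {"mets_negative": 414, "mets_positive": 741},
      "high_triglycerides": {"mets_negative": 1308, "mets_positive": 1318},
      "low_hdl": {"mets_negative": 411, "mets_positive": 709}
    }
  }
}
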