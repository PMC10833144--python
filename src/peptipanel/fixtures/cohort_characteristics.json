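{
  "description": "Per-group clinical characteristics at diagnosis (mean/sd, median/iqr or count summaries) used to seed covariate simulation",
  "groups": {
    "pFSGS": {
      "n": 19,
      "sex_male": {"kind": "count", "count": 13, "percent": 68.4},
      "age": {"kind": "mean_sd", "mean": 46.3, "sd": 16.8, "unit": "years"},
      "egfr": {"kind": "median_iqr", "median": 56.0, "q1": 37.4, "q3": 94.9, "unit": "ml/min/1.73m2"},
      "proteinuria": {"kind": "median_iqr", "median": 8.03, "q1": 5.60, "q3": 11.11, "unit": "g/d"},
      "ifta": {"kind": "mean_sd", "mean": 12.4, "sd": 11.9, "unit": "%"},
      "nephrotic_range_proteinuria": {"kind": "count", "count": 14, "percent": 73.7}
    },
    "sFSGS": {
      "n": 44,
      "sex_male": {"kind": "count", "count": 30, "percent": 68.2},
      "age": {"kind": "mean_sd", "mean": 57.6, "sd": 16.7, "unit": "years"},
      "egfr": {"kind": "median_iqr", "median": 31.1, "q1": 18.0, "q3": 43.9, "unit": "ml/min/1.73m2"},
      "proteinuria": {"kind": "median_iqr", "median": 2.56, "q1": 1.3, "q3": 4.00, "unit": "g/d"},
      "ifta": {"kind": "mean_sd", "mean": 28.3, "sd": 18.9, "unit": "%"},
      "nephrotic_range_proteinuria": {"kind": "count", "count": 14, "percent": 31.8}
    },
    "NC": {
      "n": 98,
      "sex_male": {"kind": "count", "count": 73, "percent": 74.5},
      "age": {"kind": "mean_sd", "mean": 44.7, "sd": 15.4, "unit": "years"},
      "egfr": {"kind": "median_iqr", "median": 88.4, "q1": 72.6, "q3": 114.8, "unit": "ml/min/1.73m2"},
      "proteinuria": {"kind": "median_iqr", "median": 0.01, "q1": 0.01, "q3": 0.19, "unit": "g/d"},
      "ifta": null,
      "nephrotic_range_proteinuria": {"kind": "count", "count": 0, "percent": 0.0}
    },
    "CKD_other": {
      "n": 100,
      "sex_male": {"kind": "count", "count": 73, "percent": 73.0},
      "age": {"kind": "mean_sd", "mean": 45.5, "sd": 14.7, "unit": "years"},
      "egfr": {"kind": "median_iqr", "median": 40.7, "q1": 20.9, "q3": 76.8, "unit": "ml/min/1.73m2"},
      "proteinuria": {"kind": "median_iqr", "median": 2.00, "q1": 0.69, "q3": 5.80, "unit": "g/d"},
      "ifta": {"kind": "mean_sd", "mean": 16.6, "sd": 18.9, "unit": "%"},
      "nephrotic_range_proteinuria": {"kind": "count", "count": 32, "percent": 32.0}
    }
  }
}
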