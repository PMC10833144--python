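{
  "description": "Independent non-FSGS CKD etiologies used for the specificity evaluation",
  "counts": {
    "AMYLOID": {"label": "Amyloidosis", "n": 1},
    "ATN": {"label": "Acute tubular necrosis", "n": 1},
    "DNP": {"label": "Diabetic nephropathy with nodular nephrosclerosis", "n": 66},
    "HINP": {"label": "Hypertensive ischemic nephropathy", "n": 9},
    "IGANP": {"label": "IgA nephropathy", "n": 63},
    "INTN": {"label": "Interstitial nephritis", "n": 1},
    "LN": {"label": "Lupus nephritis", "n": 3},
    "MCGN": {"label": "Minimal change glomerulopathy", "n": 6},
    "MEMGN": {"label": "Membranous nephropathy", "n": 6},
    "MPGN": {"label": "Membranoproliferative glomerulonephritis", "n": 5},
    "VASCulitis": {"label": "Vasculitis", "n": 9}
  }
}
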