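{
  "description": "Age/sex-matched non-FSGS CKD etiologies used during biomarker definition",
  "counts": {
    "AMYLOID": {"label": "Amyloidosis", "n": 4},
    "ATN": {"label": "Acute tubular necrosis", "n": 8},
    "C3MPPI_GP": {"label": "Membranoproliferative GN. C3-GN. Postinfectious GN", "n": 3},
    "CAST": {"label": "Myeloma cast nephropathy", "n": 2},
    "COLIVAD": {"label": "Collagen IV associated diseases", "n": 6},
    "DNP": {"label": "Diabetic nephropathy with nodular nephrosclerosis", "n": 10},
    "HINP": {"label": "Hypertensive ischemic nephropathy", "n": 13},
    "IGANP": {"label": "IgA nephropathy", "n": 16},
    "IGAPSH": {"label": "Henoch-Schoenlein purpura (IgA vasculitis)", "n": 5},
    "INTN": {"label": "Interstitial nephritis", "n": 6},
    "LN": {"label": "Lupus nephritis", "n": 4},
    "MCGN": {"label": "Minimal change glomerulopathy", "n": 5},
    "MEMGN": {"label": "Membranous nephropathy", "n": 9},
    "VASCular": {"label": "Thrombotic microangiopathy (cholesterol embolism)", "n": 2},
    "VASCulitis": {"label": "Vasculitis", "n": 7}
  }
}
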