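{
  "description": "Rohrer coefficients of pneumotach-2 (inhalation line) obtained from pairs of manual resuscitation-bag maneuvers with water-displacement volumetry. Maneuver 1 is the slow low-flow maneuver; each pair combines it with one of the fast maneuvers 2-5. K1 in cmH2O*s/L, K2 in cmH2O*s^2/L^2.",
  "pairs": [
    {"maneuvers": [1, 2], "K1": 0.217, "K2": 1.101},
    {"maneuvers": [1, 3], "K1": 0.209, "K2": 1.115},
    {"maneuvers": [1, 4], "K1": 0.220, "K2": 1.069},
    {"maneuvers": [1, 5], "K1": 0.215, "K2": 1.119}
  ],
  "printed_summary": {
    "K1": {"mean": 0.215, "sd": 0.005, "cv_pct": 2.7},
    "K2": {"mean": 1.101, "sd": 0.022, "cv_pct": 2.1}
  }
}
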