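{
  "description": "Syringe-calibrated Rohrer coefficients of the five drilled-channel pneumotachographs. K1 in cmH2O*s/L, K2 in cmH2O*s^2/L^2.",
  "devices": [
    {
      "name": "pneumotach-1",
      "channel_diameter_mm": 2.0,
      "channel_count": 31,
      "inhalation": {"K1": 0.343, "K2": 1.284},
      "exhalation": {"K1": 0.383, "K2": 1.323}
    },
    {
      "name": "pneumotach-2",
      "channel_diameter_mm": 2.5,
      "channel_count": 19,
      "inhalation": {"K1": 0.273, "K2": 1.232},
      "exhalation": {"K1": 0.273, "K2": 1.115}
    },
    {
      "name": "pneumotach-3",
      "channel_diameter_mm": 3.0,
      "channel_count": 19,
      "inhalation": {"K1": 0.120, "K2": 0.564},
      "exhalation": {"K1": 0.133, "K2": 0.585}
    },
    {
      "name": "pneumotach-4",
      "channel_diameter_mm": 2.5,
      "channel_count": 32,
      "inhalation": {"K1": 0.125, "K2": 0.370},
      "exhalation": {"K1": 0.129, "K2": 0.389}
    },
    {
      "name": "pneumotach-5",
      "channel_diameter_mm": 2.75,
      "channel_count": 29,
      "inhalation": {"K1": 0.089, "K2": 0.317},
      "exhalation": {"K1": 0.083, "K2": 0.297}
    }
  ]
}
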