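{
  "name": "US-5L-Pickard",
  "description": "United States societal EQ-5D-5L value set (Pickard et al. 2019). Index = 1 minus the sum of per-dimension, per-level decrements; level 1 carries no decrement.",
  "dimensions": ["mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression"],
  "decrements": {
    "mobility":           [0.0, 0.096, 0.122, 0.237, 0.322],
    "self_care":          [0.0, 0.089, 0.107, 0.220, 0.261],
    "usual_activities":   [0.0, 0.068, 0.101, 0.255, 0.255],
    "pain_discomfort":    [0.0, 0.060, 0.098, 0.318, 0.414],
    "anxiety_depression": [0.0, 0.057, 0.123, 0.299, 0.321]
  },
  "expected_floor": -0.573
}
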