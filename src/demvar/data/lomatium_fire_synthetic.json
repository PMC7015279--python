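{
  "provenance": "SYNTHETIC STAND-IN. Stage-classified vital rates for a Lomatium bradshawii-type fire-adapted perennial (Rose Prairie-style), six stages (yearling, two vegetative, three reproductive size classes) in four fire environments (fire year; 1, 2, >=3 years since fire). The published matrices are available only from the original field study; the rates below are synthetic placeholders with the published structure: reproduction confined to stages 4-6 and strongly elevated in fire years, survival increasing with size, no retrogression to the yearling stage. Replace with the published rates to reproduce the published LRO statistics.",
  "r": 0.49,
  "stage_labels": ["yearling", "veg-small", "veg-large", "repro-small", "repro-medium", "repro-large"],
  "environments": [
    {
      "label": "fire",
      "G": [[0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.75, 0.30, 0.05, 0.0, 0.0, 0.0],
            [0.25, 0.50, 0.35, 0.10, 0.0, 0.0],
            [0.0, 0.20, 0.45, 0.40, 0.10, 0.0],
            [0.0, 0.0, 0.15, 0.40, 0.55, 0.20],
            [0.0, 0.0, 0.0, 0.10, 0.35, 0.80]],
      "sigma": [0.60, 0.75, 0.85, 0.90, 0.92, 0.95],
      "fert": [0.0, 0.0, 0.0, 1.8, 4.5, 8.0]
    },
    {
      "label": "post-fire 1y",
      "G": [[0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.80, 0.40, 0.08, 0.0, 0.0, 0.0],
            [0.20, 0.45, 0.42, 0.15, 0.02, 0.0],
            [0.0, 0.15, 0.38, 0.45, 0.15, 0.02],
            [0.0, 0.0, 0.12, 0.32, 0.55, 0.25],
            [0.0, 0.0, 0.0, 0.08, 0.28, 0.73]],
      "sigma": [0.52, 0.70, 0.82, 0.88, 0.90, 0.93],
      "fert": [0.0, 0.0, 0.0, 0.9, 2.2, 4.5]
    },
    {
      "label": "post-fire 2y",
      "G": [[0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.85, 0.48, 0.10, 0.02, 0.0, 0.0],
            [0.15, 0.40, 0.45, 0.18, 0.04, 0.0],
            [0.0, 0.12, 0.35, 0.45, 0.18, 0.04],
            [0.0, 0.0, 0.10, 0.28, 0.53, 0.28],
            [0.0, 0.0, 0.0, 0.07, 0.25, 0.68]],
      "sigma": [0.46, 0.66, 0.79, 0.85, 0.88, 0.90],
      "fert": [0.0, 0.0, 0.0, 0.5, 1.4, 2.8]
    },
    {
      "label": "post-fire 3y+",
      "G": [[0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.88, 0.52, 0.12, 0.02, 0.0, 0.0],
            [0.12, 0.38, 0.46, 0.20, 0.05, 0.0],
            [0.0, 0.10, 0.32, 0.46, 0.20, 0.05],
            [0.0, 0.0, 0.10, 0.26, 0.52, 0.30],
            [0.0, 0.0, 0.0, 0.06, 0.23, 0.65]],
      "sigma": [0.40, 0.62, 0.76, 0.83, 0.86, 0.88],
      "fert": [0.0, 0.0, 0.0, 0.3, 0.9, 1.8]
    }
  ]
}
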