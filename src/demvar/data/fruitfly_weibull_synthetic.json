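{
  "provenance": "SYNTHETIC STAND-IN. Six-group Weibull frailty mixture for adult female Anastrepha obliqua longevity. The published (a, b) pairs were estimated by EM from laboratory mortality data and are not reproduced in print; the pairs below are synthetic placeholders with the same structure (scale a in days, dimensionless shape b; group 3 longest-lived). Replace with the fitted values to reproduce the published decomposition. The mixing distribution pi over frailty groups at eclosion is the published estimate.",
  "pi": [0.06, 0.20, 0.20, 0.16, 0.24, 0.14],
  "groups": [
    {"a": 26.0, "b": 1.6},
    {"a": 14.0, "b": 1.8},
    {"a": 39.0, "b": 2.1},
    {"a": 9.0, "b": 1.5},
    {"a": 17.0, "b": 2.4},
    {"a": 6.0, "b": 1.1}
  ],
  "age_cap": 200,
  "truncation_tol": 1e-10
}
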