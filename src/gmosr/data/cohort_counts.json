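{
  "provenance": "table3",
  "notes": "Published cohort composition: number of recordings per recording-age period x income band x GM category. Category order: normal, poor_repertoire, cramped_synchronized, chaotic.",
  "categories": ["normal", "poor_repertoire", "cramped_synchronized", "chaotic"],
  "counts": {
    "extremely_preterm": {"LMIC": [0, 0, 0, 0], "UMIC": [0, 8, 0, 0], "HIC": [5, 3, 0, 0]},
    "very_preterm":      {"LMIC": [2, 4, 0, 0], "UMIC": [1, 5, 1, 0], "HIC": [35, 134, 3, 0]},
    "moderate_preterm":  {"LMIC": [1, 3, 0, 0], "UMIC": [3, 9, 0, 0], "HIC": [35, 150, 32, 1]},
    "late_preterm":      {"LMIC": [6, 10, 0, 1], "UMIC": [14, 29, 7, 2], "HIC": [94, 180, 78, 16]},
    "term":              {"LMIC": [9, 26, 6, 1], "UMIC": [28, 76, 16, 2], "HIC": [71, 176, 78, 3]},
    "post_term":         {"LMIC": [32, 48, 7, 0], "UMIC": [32, 109, 11, 0], "HIC": [115, 205, 60, 0]}
  }
}
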