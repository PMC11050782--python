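{
  "provenance": "table4",
  "notes": "Recording-age-specific GMOS-R percentile anchors per income stratum (combined LMIC+UMIC vs HIC) and GM category, transcribed cell-by-cell from the published age-specific normative table. Full seven-point anchors are published only for cells with n >= 15; smaller cells are printed as not-available and carried here with null anchors (only n retained). The earliest block pools the extremely and very preterm periods (recording age < 32 weeks). The publication's cohort-composition table lists 205 poor-repertoire recordings from HICs at post-term age while the age-specific anchor table prints n = 204; both are transcribed as printed in their respective files. Chaotic GMs have no age-specific anchors (all cells below the n >= 15 threshold).",
  "strata": "income stratum (LMIC_UMIC combined vs HIC) x recording-age block",
  "entries": [
    {"income_band": "LMIC_UMIC", "period": "lt_32", "category": "normal",
     "n": 3, "min": null, "p10": null, "p25": null, "p50": null, "p75": null, "p90": null, "max": null},
    {"income_band": "LMIC_UMIC", "period": "lt_32", "category": "poor_repertoire",
     "n": 17, "min": 8, "p10": 8, "p25": 12, "p50": 14, "p75": 19, "p90": 23, "max": 24},
    {"income_band": "LMIC_UMIC", "period": "moderate_preterm", "category": "normal",
     "n": 4, "min": null, "p10": null, "p25": null, "p50": null, "p75": null, "p90": null, "max": null},
    {"income_band": "LMIC_UMIC", "period": "moderate_preterm", "category": "poor_repertoire",
     "n": 12, "min": null, "p10": null, "p25": null, "p50": null, "p75": null, "p90": null, "max": null},
    {"income_band": "LMIC_UMIC", "period": "late_preterm", "category": "normal",
     "n": 20, "min": 29, "p10": 29, "p25": 31, "p50": 32, "p75": 34, "p90": 37, "max": 37},
    {"income_band": "LMIC_UMIC", "period": "late_preterm", "category": "poor_repertoire",
     "n": 39, "min": 5, "p10": 10, "p25": 15, "p50": 20, "p75": 22, "p90": 25, "max": 27},
    {"income_band": "LMIC_UMIC", "period": "late_preterm", "category": "cramped_synchronized",
     "n": 7, "min": null, "p10": null, "p25": null, "p50": null, "p75": null, "p90": null, "max": null},
    {"income_band": "LMIC_UMIC", "period": "term", "category": "normal",
     "n": 37, "min": 29, "p10": 30, "p25": 31, "p50": 33, "p75": 34, "p90": 37, "max": 38},
    {"income_band": "LMIC_UMIC", "period": "term", "category": "poor_repertoire",
     "n": 102, "min": 6, "p10": 11, "p25": 15, "p50": 18, "p75": 23, "p90": 26, "max": 28},
    {"income_band": "LMIC_UMIC", "period": "term", "category": "cramped_synchronized",
     "n": 22, "min": 5, "p10": 6, "p25": 7, "p50": 10, "p75": 12, "p90": 13, "max": 17},
    {"income_band": "LMIC_UMIC", "period": "post_term", "category": "normal",
     "n": 64, "min": 28, "p10": 29, "p25": 31, "p50": 33, "p75": 35, "p90": 36, "max": 38},
    {"income_band": "LMIC_UMIC", "period": "post_term", "category": "poor_repertoire",
     "n": 157, "min": 10, "p10": 14, "p25": 16, "p50": 19, "p75": 22, "p90": 25, "max": 32},
    {"income_band": "LMIC_UMIC", "period": "post_term", "category": "cramped_synchronized",
     "n": 18, "min": 5, "p10": 5, "p25": 8, "p50": 9, "p75": 11, "p90": 14, "max": 17},

    {"income_band": "HIC", "period": "lt_32", "category": "normal",
     "n": 40, "min": 26, "p10": 31, "p25": 32, "p50": 34, "p75": 35, "p90": 37, "max": 38},
    {"income_band": "HIC", "period": "lt_32", "category": "poor_repertoire",
     "n": 137, "min": 9, "p10": 15, "p25": 18, "p50": 23, "p75": 28, "p90": 31, "max": 32},
    {"income_band": "HIC", "period": "moderate_preterm", "category": "normal",
     "n": 35, "min": 31, "p10": 31, "p25": 33, "p50": 35, "p75": 37, "p90": 38, "max": 38},
    {"income_band": "HIC", "period": "moderate_preterm", "category": "poor_repertoire",
     "n": 150, "min": 7, "p10": 16, "p25": 19, "p50": 23, "p75": 28, "p90": 31, "max": 32},
    {"income_band": "HIC", "period": "moderate_preterm", "category": "cramped_synchronized",
     "n": 32, "min": 2, "p10": 3, "p25": 6, "p50": 8, "p75": 12, "p90": 15, "max": 16},
    {"income_band": "HIC", "period": "late_preterm", "category": "normal",
     "n": 94, "min": 29, "p10": 32, "p25": 33, "p50": 36, "p75": 37, "p90": 38, "max": 38},
    {"income_band": "HIC", "period": "late_preterm", "category": "poor_repertoire",
     "n": 180, "min": 8, "p10": 14, "p25": 17, "p50": 21, "p75": 25, "p90": 27, "max": 32},
    {"income_band": "HIC", "period": "late_preterm", "category": "cramped_synchronized",
     "n": 78, "min": 1, "p10": 4, "p25": 5, "p50": 7, "p75": 11, "p90": 13, "max": 18},
    {"income_band": "HIC", "period": "term", "category": "normal",
     "n": 71, "min": 26, "p10": 28, "p25": 31, "p50": 35, "p75": 37, "p90": 38, "max": 38},
    {"income_band": "HIC", "period": "term", "category": "poor_repertoire",
     "n": 176, "min": 8, "p10": 14, "p25": 17, "p50": 20, "p75": 24, "p90": 28, "max": 32},
    {"income_band": "HIC", "period": "term", "category": "cramped_synchronized",
     "n": 78, "min": 3, "p10": 4, "p25": 6, "p50": 9, "p75": 11, "p90": 14, "max": 19},
    {"income_band": "HIC", "period": "post_term", "category": "normal",
     "n": 115, "min": 26, "p10": 30, "p25": 32, "p50": 34, "p75": 36, "p90": 37, "max": 38},
    {"income_band": "HIC", "period": "post_term", "category": "poor_repertoire",
     "n": 204, "min": 7, "p10": 14, "p25": 16, "p50": 20, "p75": 24, "p90": 27, "max": 32},
    {"income_band": "HIC", "period": "post_term", "category": "cramped_synchronized",
     "n": 60, "min": 1, "p10": 5, "p25": 6, "p50": 9, "p75": 12, "p90": 15, "max": 16}
  ]
}
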