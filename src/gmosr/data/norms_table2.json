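{
  "provenance": "table2",
  "notes": "Full-period GMOS-R percentile anchors per income band and GM category, transcribed cell-by-cell from the published normative table (min, P25, P50, P75, max; P10/P90 were not published at this stratification). Known transcription caveat: the publication's running-text worked examples place a score of 35 with normal GMs on P50 in HICs, whereas the typeset table prints a median of 33 for that cell; the table is transcribed as printed and the discrepancy is recorded here rather than silently resolved.",
  "strata": "income band (LMIC/UMIC/HIC), all recording ages pooled",
  "entries": [
    {"income_band": "LMIC", "period": "ALL", "category": "normal",
     "n": 50, "min": 29, "p10": null, "p25": 30, "p50": 32, "p75": 33, "p90": null, "max": 38},
    {"income_band": "UMIC", "period": "ALL", "category": "normal",
     "n": 78, "min": 28, "p10": null, "p25": 31, "p50": 33, "p75": 35, "p90": null, "max": 38},
    {"income_band": "HIC", "period": "ALL", "category": "normal",
     "n": 355, "min": 26, "p10": null, "p25": 33, "p50": 33, "p75": 37, "p90": null, "max": 38},
    {"income_band": "LMIC", "period": "ALL", "category": "poor_repertoire",
     "n": 91, "min": 8, "p10": null, "p25": 15, "p50": 19, "p75": 23, "p90": null, "max": 32},
    {"income_band": "UMIC", "period": "ALL", "category": "poor_repertoire",
     "n": 236, "min": 5, "p10": null, "p25": 15, "p50": 18, "p75": 22, "p90": null, "max": 28},
    {"income_band": "HIC", "period": "ALL", "category": "poor_repertoire",
     "n": 848, "min": 7, "p10": null, "p25": 17, "p50": 21, "p75": 25, "p90": null, "max": 32},
    {"income_band": "LMIC", "period": "ALL", "category": "cramped_synchronized",
     "n": 13, "min": 5, "p10": null, "p25": 6, "p50": 9, "p75": 11, "p90": null, "max": 12},
    {"income_band": "UMIC", "period": "ALL", "category": "cramped_synchronized",
     "n": 35, "min": 5, "p10": null, "p25": 8, "p50": 10, "p75": 13, "p90": null, "max": 18},
    {"income_band": "HIC", "period": "ALL", "category": "cramped_synchronized",
     "n": 251, "min": 1, "p10": null, "p25": 6, "p50": 8, "p75": 11, "p90": null, "max": 19},
    {"income_band": "LMIC", "period": "ALL", "category": "chaotic",
     "n": 2, "min": 11, "p10": null, "p25": null, "p50": null, "p75": null, "p90": null, "max": 16},
    {"income_band": "UMIC", "period": "ALL", "category": "chaotic",
     "n": 4, "min": 8, "p10": null, "p25": null, "p50": null, "p75": null, "p90": null, "max": 14},
    {"income_band": "HIC", "period": "ALL", "category": "chaotic",
     "n": 20, "min": 6, "p10": null, "p25": 8, "p50": 11, "p75": 15, "p90": null, "max": 22}
  ]
}
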