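{
  "version": "world-bank-snapshot-2024",
  "notes": "Frozen snapshot of the World Bank income-group assignment used when the normative tables were built; not a live classification feed.",
  "groups": {
    "HIC": [
      "Austria", "Canada", "Chile", "Czech Republic", "Denmark", "Germany",
      "Israel", "Italy", "Japan", "South Korea", "Norway", "Poland", "Qatar",
      "Spain", "Sweden", "Switzerland", "Netherlands", "United Kingdom",
      "Uruguay", "United States"
    ],
    "UMIC": [
      "Argentina", "Azerbaijan", "Brazil", "China", "Colombia", "Kazakhstan",
      "Mexico", "Peru", "South Africa", "Turkey"
    ],
    "LMIC": [
      "Bangladesh", "Bolivia", "Cambodia", "Egypt", "India", "Iran", "Nepal"
    ]
  },
  "aliases": {
    "USA": "United States",
    "US": "United States",
    "United States of America": "United States",
    "UK": "United Kingdom",
    "Great Britain": "United Kingdom",
    "Korea": "South Korea",
    "Republic of Korea": "South Korea",
    "The Netherlands": "Netherlands",
    "Holland": "Netherlands",
    "Czechia": "Czech Republic",
    "Türkiye": "Turkey",
    "Turkiye": "Turkey"
  }
}
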