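{
  "name": "gmosr-default",
  "notes": "Default GMOS-R scoresheet structure. Region composition, item counts, permitted values and subscore maxima follow the published instrument (8 items per extremity region after removal of the tremulous-movements item, 2 neck/trunk items, 1 sequence item; total maximum 38). The extremity item names are reconstructed from the instrument's running description (amplitude, speed, spatial range, rotations, beginning, end, stiffness, plus overall variability); deployments transcribing the official scoresheet may override this file.",
  "regions": [
    {
      "name": "UPPER_EXTREMITIES",
      "items": ["amplitude", "speed", "spatial_range", "rotations",
                "variability", "beginning", "end", "stiffness"],
      "allowed_values": [0, 0.5, 1, 1.5, 2],
      "subscore_max": 16
    },
    {
      "name": "LOWER_EXTREMITIES",
      "items": ["amplitude", "speed", "spatial_range", "rotations",
                "variability", "beginning", "end", "stiffness"],
      "allowed_values": [0, 0.5, 1, 1.5, 2],
      "subscore_max": 16
    },
    {
      "name": "NECK_AND_TRUNK",
      "items": ["neck", "trunk"],
      "allowed_values": [0, 0.5, 1, 1.5, 2],
      "subscore_max": 4
    },
    {
      "name": "SEQUENCE",
      "items": ["sequence"],
      "allowed_values": [0, 1, 2],
      "subscore_max": 2
    }
  ]
}
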