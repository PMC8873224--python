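{
  "scheme": "ICDRS",
  "levels": ["0", "1", "2", "3", "4"],
  "level_names": {
    "0": "no retinopathy",
    "1": "mild NPDR",
    "2": "moderate NPDR",
    "3": "severe NPDR",
    "4": "PDR"
  },
  "rules": [
    {
      "level": "4",
      "any": [
        {"present": ["NVD", "NVE", "PRERETINAL_HAEMORRHAGE", "FIBROSIS", "SCAR"]}
      ]
    },
    {
      "level": "3",
      "any": [
        {"lesions": ["HAEMORRHAGE", "BLOT_HAEMORRHAGE"], "min_per_quadrant": 20, "min_quadrants": 4},
        {"lesion": "VENOUS_BEADING", "min_quadrants_present": 2},
        {"lesion": "IRMA", "min_quadrants_present": 1}
      ]
    },
    {
      "level": "2",
      "any": [
        {"present": ["HAEMORRHAGE", "BLOT_HAEMORRHAGE", "EXUDATE", "CWS", "VENOUS_LOOP", "VENOUS_REDUPLICATION", "VENOUS_BEADING"]}
      ]
    },
    {
      "level": "1",
      "any": [
        {"lesion": "MA", "min_count": 1}
      ]
    },
    {"level": "0", "default": true}
  ]
}
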