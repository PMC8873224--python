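{
  "scheme": "NSC",
  "levels": ["R0", "R1", "R2", "R3"],
  "level_names": {
    "R0": "no retinopathy",
    "R1": "background",
    "R2": "pre-proliferative",
    "R3": "proliferative"
  },
  "rules": [
    {
      "level": "R3",
      "any": [
        {"present": ["NVD", "NVE", "PRERETINAL_HAEMORRHAGE", "FIBROSIS", "SCAR"]}
      ]
    },
    {
      "level": "R2",
      "any": [
        {"present": ["VENOUS_BEADING", "VENOUS_LOOP", "VENOUS_REDUPLICATION", "IRMA"]},
        {"lesion": "BLOT_HAEMORRHAGE", "min_count": 5}
      ]
    },
    {
      "level": "R1",
      "any": [
        {"present": ["MA", "HAEMORRHAGE", "BLOT_HAEMORRHAGE", "EXUDATE", "CWS"]}
      ]
    },
    {"level": "R0", "default": true}
  ]
}
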