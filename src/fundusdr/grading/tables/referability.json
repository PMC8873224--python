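{
  "ICDRS": {"referable_levels": ["2", "3", "4"], "dmo_referable": true},
  "NSC": {"referable_levels": ["R2", "R3"], "dmo_referable": true}
}
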