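{
  "JA": {
    "genes": ["ZIK1", "MEKK3_2", "MEKK5_1", "MEKK10_1", "MEKK17", "MEKK20", "CTR1_1", "RAF30_1", "RAF32", "RAF38_3"],
    "ambiguous": false
  },
  "H2O2": {
    "genes": ["ZIK1", "MEKK3_2", "MEKK17", "MEKK20", "CTR1_1", "RAF30_1", "RAF32"],
    "ambiguous": false
  },
  "ABA": {
    "genes": ["ZIK1", "MEKK4_2", "MEKK5_1", "MEKK10_1", "MEKK17", "MEKK20", "RAF30_1", "RAF32", "RAF38_3"],
    "ambiguous": true,
    "note": "reported count is ten but only nine distinct genes are enumerated (RAF32 appears at two peak times); excluded from acceptance checks"
  },
  "SA": {
    "genes": ["ZIK1", "MEKK3_2", "MEKK4_2", "MEKK10_1", "MEKK17", "MEKK20", "CTR1_1", "RAF32", "RAF38_3"],
    "ambiguous": true,
    "note": "the nine SA-induced genes are never enumerated directly; this list is reconstructed from cross-treatment summary statements and is not used in acceptance checks"
  },
  "NaCl": {
    "genes": ["ZIK1", "MEKK3_2", "MEKK4_2", "MEKK5_1", "MEKK10_1", "MEKK17", "MEKK20", "RAF30_1", "RAF31_1", "RAF32", "RAF38_3"],
    "ambiguous": false
  },
  "PEG": {
    "genes": ["MEKK10_1", "MEKK17", "MEKK20", "CTR1_1"],
    "ambiguous": false
  },
  "cold_4C": {
    "genes": ["ZIK1", "MEKK3_2", "MEKK10_1", "MEKK17", "RAF32"],
    "ambiguous": false
  },
  "heat_37C": {
    "genes": ["MEKK3_2", "MEKK4_2", "MEKK17", "RAF31_1", "RAF32", "RAF38_3"],
    "ambiguous": false
  },
  "wounding": {
    "genes": ["ZIK1", "MEKK3_2", "MEKK4_2", "MEKK5_1", "MEKK17", "MEKK20", "CTR1_1", "RAF31_1", "RAF32"],
    "ambiguous": false
  }
}
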