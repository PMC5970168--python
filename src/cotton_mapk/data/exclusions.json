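{
  "exclusions": ["MKK10_1", "MEKK19", "RAF17_2"],
  "reasons": {
    "MKK10_1": "expression too low to detect in all tissues",
    "MEKK19": "low expression in leaf and <2-fold change under all stresses",
    "RAF17_2": "low expression in leaf and <2-fold change under all stresses"
  }
}
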