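{
  "_comment": "Per-gene stress-response profiles transcribed from the published cascade narrative; MAPK-tier inductions come from companion MKK/MAPK family studies and carry provenance 'fixture'.",
  "profiles": {
    "ZIK1": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MEKK3_2": {"induced": ["JA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MEKK4_2": {"induced": ["JA", "ABA", "SA", "NaCl", "heat_37C", "wounding"], "provenance": "fixture"},
    "MEKK5_1": {"induced": ["JA", "ABA", "NaCl", "wounding"], "provenance": "fixture"},
    "MEKK10_1": {"induced": ["JA", "ABA", "SA", "NaCl", "cold_4C", "heat_37C"], "provenance": "fixture"},
    "MEKK17": {"induced": ["JA", "ABA", "H2O2", "NaCl", "PEG", "heat_37C", "wounding"], "provenance": "fixture"},
    "MEKK20": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "wounding"], "provenance": "fixture"},
    "RAF30_1": {"induced": ["JA", "ABA", "H2O2", "NaCl", "heat_37C"], "provenance": "fixture"},
    "RAF31_1": {"induced": ["ABA", "NaCl", "wounding"], "provenance": "fixture"},
    "RAF38_3": {"induced": ["JA", "ABA", "NaCl"], "provenance": "fixture"},
    "MPK3": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK6": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK7": {"induced": ["JA", "ABA", "H2O2", "NaCl", "PEG", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK8": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "wounding"], "provenance": "fixture"},
    "MPK12": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK13": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK15": {"induced": ["JA", "ABA", "H2O2", "NaCl", "PEG", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK18": {"induced": ["JA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK20": {"induced": ["JA", "ABA", "H2O2", "SA", "NaCl", "PEG", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK23": {"induced": ["JA", "H2O2", "SA", "NaCl", "cold_4C", "heat_37C", "wounding"], "provenance": "fixture"},
    "MPK25": {"induced": ["JA", "ABA", "H2O2", "NaCl", "PEG", "heat_37C", "wounding"], "provenance": "fixture"}
  }
}
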