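{
  "exclusions.json": "64e7b1bf1b992bf4ef9cd8f2f6da7558137ec5fc15a5acc9bfa04d513270559a",
  "induced_genes.json": "b31a736032c02599a3811094afd57a762dc84da9d64a1e0a0f411424106abb45",
  "interactions.tsv": "96b24da4fc06ca3fe2aae23a05188d78409414586b13bdf567448b7e7f8ba4f9",
  "response_profiles.json": "7d04f26dcbcd364abfb5a2f145fa43b7bd5d73013c0b2c5a3697aceff16f84cb"
}
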