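{
 "schema_version": 1,
 "name": "marconi-classification",
 "kind": "marconi",
 "seed": 1,
 "options": {"n_peptides": 53, "ligands": ["DEX", "RU486", "CYP"], "cv": 0.05, "alpha_level": 0.01}
}
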