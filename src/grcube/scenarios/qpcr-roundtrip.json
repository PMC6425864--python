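{
 "schema_version": 1,
 "name": "qpcr-roundtrip",
 "kind": "qpcr",
 "seed": 1,
 "options": {"true_folds": {"DEX": 4.0}, "cp_sd": 0.15, "eff_target": 2.0, "eff_reference": 2.0}
}
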