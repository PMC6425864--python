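{
 "schema_version": 1,
 "name": "competition",
 "kind": "competition",
 "seed": 1,
 "shared": {"Kc": 1e9, "Kd": 1e9, "beta": 1.0},
 "agonist": {"name": "DEX", "Ka": 2.3e9, "alpha": 1.0, "gamma": 1.0, "delta": 1.0},
 "modulator": {"name": "RU486", "Ka": 6.0e8, "alpha": 1.0, "gamma": 1.0, "delta": 1.0},
 "milieu": {"L": 0.0, "C": 1e-9, "D": 1e-9, "Rtot": 1.0},
 "options": {"modulator_dose_M": 1e-7, "efficacies": {"DEX": 1.0, "RU486": 0.15}, "epsilon": 132.0, "cv": 0.1}
}
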