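{
 "schema_version": 1,
 "name": "receptor-knockdown",
 "kind": "receptor-knockdown",
 "seed": 1,
 "params": {"Ka": 2.3e9, "Kc": 1e9, "Kd": 1e9, "alpha": 1.0, "beta": 1.0, "gamma": 1.0, "delta": 1.0},
 "milieu": {"L": 0.0, "C": 1e-9, "D": 1e-9, "Rtot": 1.0},
 "response": {"coefficients": {"LRCD": 1.0}, "epsilon": 132.0},
 "options": {"scales": [1.0, 0.58, 0.15]}
}
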