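{
 "schema_version": 1,
 "name": "sensitivity-scan",
 "kind": "sensitivity-scan",
 "seed": 1,
 "params": {
  "Ka": 100000000.0,
  "Kc": 1000000000.0,
  "Kd": 1000000000.0,
  "alpha": 1.0,
  "beta": 0.005623413251903491,
  "gamma": 1.0,
  "delta": 1.0
 },
 "milieu": {
  "L": 0.0,
  "C": 1e-05,
  "D": 1e-05,
  "Rtot": 1.0
 },
 "response": {
  "coefficients": {
   "LRCD": 1.0
  },
  "epsilon": 34.0
 },
 "options": {
  "fold_range": 100.0,
  "threshold": 1.25,
  "parameters": [
   "alpha",
   "beta",
   "gamma",
   "delta"
  ]
 }
}
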