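{
 "schema_version": 1,
 "name": "coregulator-knockdown",
 "kind": "coregulator-knockdown",
 "seed": 1,
 "params": {
  "Ka": 1000000000.0,
  "Kc": 1000000000.0,
  "Kd": 1000000000.0,
  "alpha": 1.0,
  "beta": 1.0,
  "gamma": 1.0,
  "delta": 49.10168126727387
 },
 "milieu": {
  "L": 0.0,
  "C": 2.9999999999999995e-10,
  "D": 2.9999999999999995e-10,
  "Rtot": 1.0
 },
 "response": {
  "coefficients": {
   "LRCD": 1.0
  },
  "epsilon": 6.7
 },
 "options": {
  "scales": [
   1.0,
   0.1
  ],
  "threshold": 1.25
 }
}
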