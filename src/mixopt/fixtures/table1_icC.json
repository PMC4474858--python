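{
 "q": 3,
 "points": [
  [
   1.0,
   0.0,
   0.0
  ],
  [
   0.0,
   1.0,
   0.0
  ],
  [
   0.0,
   0.0,
   1.0
  ],
  [
   0.0,
   0.2764,
   0.7236
  ],
  [
   0.2764,
   0.0,
   0.7236
  ],
  [
   0.7236,
   0.0,
   0.2764
  ],
  [
   0.0,
   0.7236,
   0.2764
  ],
  [
   0.5,
   0.5,
   0.0
  ]
 ],
 "weights": [
  0.125,
  0.125,
  0.125,
  0.125,
  0.125,
  0.125,
  0.125,
  0.125
 ],
 "note": "D-optimal design, incomplete cubic model C"
}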