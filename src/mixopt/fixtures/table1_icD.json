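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
  ],
  [
   0.3333,
   0.3333,
   0.3333
  ]
 ],
 "weights": [
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.111111
 ],
 "note": "D-optimal design, incomplete cubic model D"
}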