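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
   0.2764,
   0.7236
  ],
  [
   0.0,
   0.7236,
   0.2764
  ],
  [
   0.2113,
   0.7887,
   0.0
  ],
  [
   0.7887,
   0.2113,
   0.0
  ],
  [
   0.3333,
   0.3333,
   0.3333
  ]
 ],
 "weights": [
  0.083333,
  0.083333,
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.111111,
  0.083333,
  0.083333,
  0.111111
 ],
 "note": "D-optimal design, incomplete cubic model A; the four 0.1111 edge points sit on the x1-x3 and x2-x3 edges (one published point is misprinted on the x1-x2 edge)"
}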