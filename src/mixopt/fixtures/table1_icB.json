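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
   0.0,
   0.7236,
   0.2764
  ],
  [
   0.7887,
   0.2113,
   0.0
  ],
  [
   0.7887,
   0.0,
   0.2113
  ],
  [
   0.2113,
   0.7887,
   0.0
  ],
  [
   0.2113,
   0.0,
   0.7887
  ],
  [
   0.3333,
   0.3333,
   0.3333
  ]
 ],
 "weights": [
  0.0625,
  0.09375,
  0.09375,
  0.125,
  0.125,
  0.09375,
  0.09375,
  0.09375,
  0.09375,
  0.125
 ],
 "note": "D-optimal design, incomplete cubic model B; vertex (1,0,0) carries 1/16 (the published uniform 0.0938 x3 vertex row is inconsistent: the weights are 1/16, 3/32, 3/32, 3/32 x4, 1/8 x3; stored exactly)"
}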