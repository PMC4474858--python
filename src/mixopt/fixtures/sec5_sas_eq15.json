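{
 "q": 3,
 "points": [
  [
   0.0,
   0.0,
   1.0
  ],
  [
   0.0,
   0.49,
   0.51
  ],
  [
   0.0,
   1.0,
   0.0
  ],
  [
   0.27,
   0.29,
   0.44
  ],
  [
   0.28,
   0.0,
   0.72
  ],
  [
   0.28,
   0.72,
   0.0
  ],
  [
   0.7,
   0.0,
   0.3
  ],
  [
   0.73,
   0.27,
   0.0
  ],
  [
   1.0,
   0.0,
   0.0
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
 "note": "equally weighted 9-point exchange-algorithm design on a 101-level grid"
}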