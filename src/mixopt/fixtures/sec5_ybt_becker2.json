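{
 "q": 3,
 "points": [
  [
   0.0,
   0.001,
   0.999
  ],
  [
   0.001,
   0.0,
   0.999
  ],
  [
   0.0,
   0.5,
   0.5
  ],
  [
   0.0,
   0.999,
   0.001
  ],
  [
   0.001,
   0.999,
   0.0
  ],
  [
   0.333,
   0.333,
   0.334
  ],
  [
   0.334,
   0.333,
   0.333
  ],
  [
   0.5,
   0.0,
   0.5
  ],
  [
   0.5,
   0.5,
   0.0
  ],
  [
   0.999,
   0.0,
   0.001
  ],
  [
   0.999,
   0.001,
   0.0
  ]
 ],
 "weights": [
  0.0714,
  0.0714,
  0.1429,
  0.0714,
  0.0714,
  0.0714,
  0.0714,
  0.1429,
  0.1429,
  0.0714,
  0.0714
 ],
 "note": "11-point grid-exchange design for the Becker ratio model; the published weight vector's final entry (0.1429) is corrected to 0.0714 so the weights sum to one"
}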