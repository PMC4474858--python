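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
   0.5,
   0.5,
   0.0
  ],
  [
   0.5,
   0.0,
   0.5
  ],
  [
   0.0,
   0.5,
   0.5
  ],
  [
   0.3333,
   0.3333,
   0.3333
  ]
 ],
 "weights": [
  0.142857,
  0.142857,
  0.142857,
  0.142857,
  0.142857,
  0.142857,
  0.142857
 ],
 "note": "D-optimal design for Becker model 3 (3 components)"
}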