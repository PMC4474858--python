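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
   0.1175,
   0.8825,
   0.0
  ],
  [
   0.8825,
   0.1175,
   0.0
  ],
  [
   0.3574,
   0.6426,
   0.0
  ],
  [
   0.6426,
   0.3574,
   0.0
  ]
 ],
 "weights": [
  0.166667,
  0.166667,
  0.166667,
  0.166667,
  0.166667,
  0.166667
 ],
 "note": "D-optimal design, Kasatkin 5th-order polynomial"
}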