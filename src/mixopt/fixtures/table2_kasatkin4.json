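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
   0.1727,
   0.8273,
   0.0
  ],
  [
   0.8273,
   0.1727,
   0.0
  ],
  [
   0.5,
   0.5,
   0.0
  ]
 ],
 "weights": [
  0.2,
  0.2,
  0.2,
  0.2,
  0.2
 ],
 "note": "D-optimal design, Kasatkin 4th-order polynomial"
}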