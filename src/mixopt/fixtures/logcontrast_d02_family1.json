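{
 "q": 3,
 "points": [
  [
   0.7143,
   0.1429,
   0.1429
  ],
  [
   0.1429,
   0.7143,
   0.1429
  ],
  [
   0.1429,
   0.1429,
   0.7143
  ]
 ],
 "weights": [
  0.333333,
  0.333333,
  0.333333
 ],
 "note": "D-optimal design, 3-component linear log-contrast model, ratio bound delta=0.2, vertex-adjacent family"
}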