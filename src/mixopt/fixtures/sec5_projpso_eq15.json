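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
   1.0,
   0.0
  ],
  [
   0.2774,
   0.2491,
   0.4735
  ],
  [
   0.0,
   0.4946,
   0.5054
  ],
  [
   0.2723,
   0.0,
   0.7277
  ],
  [
   0.6991,
   0.0,
   0.3009
  ],
  [
   0.7238,
   0.2762,
   0.0
  ],
  [
   0.2767,
   0.7233,
   0.0
  ],
  [
   1.0,
   0.0,
   0.0
  ]
 ],
 "weights": [
  0.1198,
  0.1249,
  0.0802,
  0.1182,
  0.0647,
  0.1212,
  0.121,
  0.125,
  0.125
 ],
 "note": "swarm-generated weighted 9-point D-optimal design, 8-term incomplete cubic with intercept"
}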