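{
 "q": 3,
 "points": [
  [
   0.1,
   0.8,
   0.1
  ],
  [
   0.2,
   0.5,
   0.3
  ],
  [
   0.3,
   0.2,
   0.5
  ],
  [
   0.4,
   0.5,
   0.1
  ],
  [
   0.5,
   0.1,
   0.4
  ],
  [
   0.6,
   0.2,
   0.2
  ],
  [
   0.7,
   0.3,
   0.0
  ],
  [
   0.8,
   0.1,
   0.1
  ]
 ],
 "weights": [
  0.125,
  0.125,
  0.125,
  0.125,
  0.125,
  0.125,
  0.125,
  0.125
 ],
 "note": "equally weighted 8-run first-stage design for the Becker geometric-mean model"
}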