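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
   0.486,
   0.514
  ],
  [
   0.0,
   0.487,
   0.513
  ],
  [
   0.0,
   1.0,
   0.0
  ],
  [
   0.438,
   0.562,
   0.0
  ],
  [
   0.487,
   0.0,
   0.513
  ],
  [
   0.488,
   0.0,
   0.512
  ],
  [
   1.0,
   0.0,
   0.0
  ]
 ],
 "weights": [
  0.1992,
  0.1463,
  0.0417,
  0.1768,
  0.083,
  0.1382,
  0.0386,
  0.1762
 ],
 "note": "grid-exchange second-stage design for the same augmentation problem (1001-level grid)"
}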