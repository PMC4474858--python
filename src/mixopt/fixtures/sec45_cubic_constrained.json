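{
 "q": 3,
 "points": [
  [
   0.5,
   0.5,
   0.0
  ],
  [
   0.3645,
   0.3178,
   0.3178
  ],
  [
   0.0,
   0.0,
   1.0
  ],
  [
   0.2135,
   0.7865,
   0.0
  ],
  [
   0.5,
   0.0,
   0.5
  ],
  [
   0.0,
   1.0,
   0.0
  ],
  [
   0.0,
   0.2764,
   0.7236
  ],
  [
   0.2135,
   0.0,
   0.7865
  ],
  [
   0.0,
   0.7236,
   0.2764
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
 "note": "equally weighted 9-point D-optimal design for the cubic model without 3-way effect under x1 <= 0.5"
}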