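{
 "q": 6,
 "points": [
  [
   0.0,
   0.0,
   0.3129,
   0.0,
   0.0,
   0.6871
  ],
  [
   0.0,
   0.0,
   0.0,
   0.8094,
   0.1906,
   0.0
  ],
  [
   0.1906,
   0.0,
   0.0,
   0.8094,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.3129,
   0.6871
  ],
  [
   0.0,
   0.4925,
   0.0,
   0.0,
   0.5075,
   0.0
  ],
  [
   0.4522,
   0.0,
   0.5478,
   0.0,
   0.0,
   0.0
  ],
  [
   0.4925,
   0.0,
   0.0,
   0.0,
   0.5075,
   0.0
  ],
  [
   0.6133,
   0.0,
   0.0,
   0.0,
   0.0,
   0.3867
  ],
  [
   0.0,
   0.0,
   0.5439,
   0.0,
   0.0,
   0.4561
  ],
  [
   0.0,
   0.0,
   0.0,
   0.8094,
   0.0,
   0.1906
  ],
  [
   0.6131,
   0.0,
   0.0,
   0.3869,
   0.0,
   0.0
  ],
  [
   0.0,
   0.8572,
   0.1428,
   0.0,
   0.0,
   0.0
  ],
  [
   0.1428,
   0.8572,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 ],
 "weights": [
  0.0885,
  0.0825,
  0.0208,
  0.0931,
  0.0325,
  0.0988,
  0.1005,
  0.0783,
  0.0007,
  0.0553,
  0.0332,
  0.0845,
  0.0781
 ],
 "note": "13-point weighted swarm design for the 6-component first-order model with upper bounds (0.6133, 0.8572, 0.5478, 0.8094, 0.5075, 0.6871); the published weight vector sums to 0.8468 (a printing defect) and is renormalized on load",
 "renormalize": true
}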