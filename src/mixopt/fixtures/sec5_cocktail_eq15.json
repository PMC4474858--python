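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
   0.495,
   0.505
  ],
  [
   0.0,
   1.0,
   0.0
  ],
  [
   0.272,
   0.0,
   0.728
  ],
  [
   0.277,
   0.249,
   0.474
  ],
  [
   0.277,
   0.723,
   0.0
  ],
  [
   0.278,
   0.249,
   0.473
  ],
  [
   0.699,
   0.0,
   0.301
  ],
  [
   0.724,
   0.276,
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
  0.1182,
  0.1249,
  0.0647,
  0.0566,
  0.125,
  0.0236,
  0.1212,
  0.121,
  0.125
 ],
 "note": "10-point design from the vertex-direction/multiplicative (cocktail) run on a 1001-level grid; points 5 and 7 are a mergeable pair"
}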