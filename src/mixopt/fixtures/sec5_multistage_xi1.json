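{
 "q": 3,
 "points": [
  [
   0.0,
   0.0,
   1.0
  ],
  [
   0.4874,
   0.0,
   0.5126
  ],
  [
   0.0,
   1.0,
   0.0
  ],
  [
   0.0,
   0.4864,
   0.5136
  ],
  [
   1.0,
   0.0,
   0.0
  ],
  [
   0.4385,
   0.5615,
   0.0
  ]
 ],
 "weights": [
  0.1992,
  0.1768,
  0.1769,
  0.188,
  0.1762,
  0.083
 ],
 "note": "swarm second-stage design augmenting the 8-run first stage (n0=n1=8); the published second coordinate of the sixth point (0.5165) is corrected to 0.5615 so the point lies on the simplex (digit transposition), and the weights are paired to points as confirmed by the independently published grid-exchange solution ((0,0,1) carries 0.1992, (1,0,0) carries 0.1762; the article lists the same weight multiset in a different order)"
}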