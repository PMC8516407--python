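# Upstream anaerobic corrin-ring biosynthesis module M00924:
# uroporphyrinogen III -> sirohydrochlorin -> cobyrinate a,c-diamide.
# Gene blocks as annotated in corrinoid-producing hydrogenotrophic
# methanogens (cysG, cbi cluster, cfbA, cob ring-methylation genes).
name: M00924
blocks:
  - {name: cysG, alternatives: [cysg]}
  - {name: cbiC, alternatives: [cbic]}
  - {name: cbiD, alternatives: [cbid]}
  - {name: cbiE, alternatives: [cbie]}
  - {name: cbiG, alternatives: [cbig]}
  - {name: cbiL, alternatives: [cbil]}
  - {name: cbiM, alternatives: [cbim]}
  - {name: cbiQ, alternatives: [cbiq]}
  - {name: cbiT, alternatives: [cbit]}
  - {name: cfbA, alternatives: [cfba]}
  - {name: cobI, alternatives: [cobi]}
  - {name: cobM, alternatives: [cobm]}
  - {name: cobJ, alternatives: [cobj]}
  - {name: cobK, alternatives: [cobk]}
  - {name: cobH, alternatives: [cobh]}
  - {name: cobB, alternatives: [cobb]}
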