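# Hydrogenase complex detection by gene-symbol prefix. A complex is
# reported iff >=1 record's symbol starts with one of its prefixes.
# Prefixes are tested against the whole lowercased symbol string, so a
# fused annotation like "hypC/hybG/hupF" counts only toward Hyp.
name: hydrogenase_complexes
complexes:
  Hyp: [hyp]
  Hyc: [hyc, hyb]
  Hym: [hym]
  Vhu: [vhu]
  Ech: [ech]
  Hup: [hup]
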