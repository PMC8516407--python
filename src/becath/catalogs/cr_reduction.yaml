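# Cr(VI)-to-Cr(III) bioreduction machinery.
# Extracellular route: complete mtrCAB electron conduit plus at least one
# c-type cytochrome feeding it. Intracellular route: ABC transport system
# (>=1 ATP-dependent component and >=1 permease) importing chromate plus
# an NADPH-dependent F420/FMN reductase (npdG) reducing it in the cytosol.
name: cr_reduction
extracellular:
  required_symbols: [mtra, mtrb, mtrc]
  cytochrome_keywords: ["cytochrome c", "c type cytochrome", "c cytochrome"]
intracellular:
  atp_dependent_keywords:
    ["abc transporter atp", "abc transporter, atp", "atp binding cassette"]
  permease_keywords: ["abc transporter permease", "transporter permease"]
  reductase_symbols: [npdg]
  reductase_keywords:
    ["nadph dependent f420 reductase", "nadph dependent fmn reductase"]
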