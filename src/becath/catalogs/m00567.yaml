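# Hydrogenotrophic methanogenesis module M00567 (CO2 + 4 H2 -> CH4).
# Each block is one enzymatic step; alternatives are symbol prefixes so
# multi-subunit operons (fwdA..D, mcrABG, mtrA-H, frhABGD) hit via any
# subunit. ftr and fhcD are alternative annotations of the same
# formyltransferase step.
name: M00567
blocks:
  - {name: fwd (formylmethanofuran dehydrogenase), alternatives: [fwd]}
  - {name: ftr (formylmethanofuran--H4MPT formyltransferase), alternatives: [ftr, fhcd]}
  - {name: mch (methenyl-H4MPT cyclohydrolase), alternatives: [mch]}
  - {name: mtd (F420-dependent methylene-H4MPT dehydrogenase), alternatives: [mtd]}
  - {name: mer (methylene-H4MPT reductase), alternatives: [mer]}
  - {name: mtr (H4MPT S-methyltransferase), alternatives: [mtr]}
  - {name: mcr (methyl-coenzyme M reductase), alternatives: [mcr]}
  - {name: frh (F420-reducing hydrogenase), alternatives: [frh]}
  - {name: mvh (F420-non-reducing hydrogenase), alternatives: [mvh]}
  - {name: hdr (heterodisulfide reductase), alternatives: [hdr]}
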