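# Dehalogenase classification rules for organohalide-respiring genomes.
# Classes are tried in order; a record is counted once in the first class
# it matches (anchor > haloacid > catalytic > hypothetical), which prevents
# double counting since every class keyword contains "dehalogenase".
name: dehalogenase_inventory
classes:
  - class: anchor_rdhB
    symbols: [rdhb]
    keywords: ["membrane anchoring subunit rdhb", "membrane anchor"]
  - class: haloacid_dehalogenase
    symbols: []
    keywords: ["haloacid dehalogenase"]
  - class: catalytic_rdhA
    symbols: [rdha, tcea, vcra, bvca]
    keywords: ["reductive dehalogenase"]
  - class: hypothetical_dehalogenase
    symbols: []
    keywords: ["dehalogenase"]
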