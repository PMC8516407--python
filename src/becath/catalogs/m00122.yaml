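# Downstream (aerobic/anaerobic-shared) corrinoid biosynthesis module
# M00122: cobyrinate a,c-diamide -> vitamin B12 coenzyme. Block list from
# the cob gene complement of downstream-only corrinoid auxotrophs such as
# D. mccartyi. Completeness = fraction of blocks with >=1 alternative hit.
name: M00122
blocks:
  - name: cobC
    alternatives: [cobc]
  - name: cobD
    alternatives: [cobd]
  - name: cobU
    alternatives: [cobu]
  - name: cobS
    alternatives: [cobs]
  - name: cobT
    alternatives: [cobt]
  - name: cobN
    alternatives: [cobn]
# B12 salvage transport, reported separately from pathway completeness.
transport_symbols: [btuf]
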