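# Dehalogenase gene complement of the D. mccartyi genome bin recovered
# from the TCE/Cr(VI) biocathode metagenome (GenBank JADIIK000000000):
# 13 catalytic rdhA genes, 1 membrane-anchor rdhB, 14 hypothetical
# dehalogenases and 1 haloacid dehalogenase. Identities are versus the
# closest characterized reductive dehalogenase; ortholog groups from the
# RDase database.
locus_id	gene	product	identity	ortholog_group
MBF4481786	rdhA	reductive dehalogenase	99.60	33
MBF4481792	rdhA	reductive dehalogenase	98.20	75
MBF4481797	rdhA	reductive dehalogenase	98.40	34
MBF4482477	rdhA	reductive dehalogenase (expressed during starvation homolog)	99.80	15
MBF4482483	rdhA	reductive dehalogenase	99.40	17
MBF4481809	rdhA	reductive dehalogenase	99.80	10
MBF4481838	rdhA	reductive dehalogenase	94.50	17
MBF4482084	rdhA	reductive dehalogenase	99.20	nd
MBF4481750	rdhA	reductive dehalogenase	96.20	19
MBF4481754	rdhA	reductive dehalogenase	95.90	40
MBF4481741	rdhA	reductive dehalogenase	99.60	76
MBF4481742	rdhA	reductive dehalogenase	96.20	81
MBF4482271	rdhA	TceA reductive dehalogenase catalytic subunit	99.64	5
MBF4482272	rdhB	reductive dehalogenase membrane-anchoring subunit RdhB	100
MBF4481743		dehalogenase hypothetical protein
MBF4481749		dehalogenase hypothetical protein
MBF4481753		dehalogenase hypothetical protein
MBF4481785		dehalogenase hypothetical protein
MBF4481791		dehalogenase hypothetical protein
MBF4481796		dehalogenase hypothetical protein
MBF4481808		dehalogenase hypothetical protein
MBF4482083		dehalogenase hypothetical protein
MBF4482154		dehalogenase hypothetical protein
MBF4482216		dehalogenase hypothetical protein
MBF4482478		dehalogenase hypothetical protein
MBF4482484		dehalogenase hypothetical protein
MBF4481814		dehalogenase hypothetical protein
MBF4481844		dehalogenase hypothetical protein
MBF4482892		haloacid dehalogenase
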