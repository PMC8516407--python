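# Anaerobic cobalamin-synthesis genes of the D. mccartyi genome bin from
# the TCE/Cr(VI) biocathode (GenBank JADIIK000000000): the downstream
# cob complement (M00122), cbiD/cbiE from the upstream module M00924,
# four ring-methylation genes shared with the aerobic route, and the
# btuF B12 salvage transporter component.
locus_id	gene	product
MBF4482113	cbiE	Precorrin-6y C5,15-methyltransferase (decarboxylating) subunit CbiE
MBF4481778	cbiD	Cobalt-precorrin-5B (C(1))-methyltransferase
MBF4481765	cobH	Precorrin-8X methylmutase
MBF4481776	cobI	Precorrin-2 C(20)-methyltransferase
MBF4481774	cobJ	Precorrin-3B C(17)-methyltransferase
MBF4481775	cobM	Precorrin-4 C(11)-methyltransferase
MBF4482814	cobC	Alpha-ribazole phosphatase
MBF4482117	cobD	Cobalamin biosynthesis protein CobD
MBF4482815	cobU	Bifunctional adenosylcobinamide kinase/adenosylcobinamide-phosphate guanylyltransferase
MBF4482813	cobS	Adenosylcobinamide-GDP ribazoletransferase
MBF4482812	cobT	Nicotinate-nucleotide--dimethylbenzimidazole phosphoribosyltransferase
MBF4481784	cobN	Cobaltochelatase subunit CobN
MBF4482806	btuF	Vitamin B12 ABC transporter, B12-binding component BtuF
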