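# CRISPR-system genes of the D. mccartyi genome bin from the TCE/Cr(VI)
# biocathode (GenBank JADIIK000000000): four cas genes plus the LexA
# regulator (auxiliary). Identities versus the RefSeq products shown.
locus_id	gene	product	identity	ortholog_group
MBF4481735	cas3	CRISPR-associated helicase/endonuclease Cas3	98.45
MBF4481736	cse1	type I-E CRISPR-associated protein Cse1/CasA	45.18
MBF4481737	cas2	type I-E CRISPR-associated endoribonuclease Cas2	88.68
MBF4482064	cas3	CRISPR-associated helicase Cas3	96.65
MBF4482400		LexA family transcriptional regulator	100
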