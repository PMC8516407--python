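# Hydrogenotrophic methanogenesis (module M00567) gene complement shared
# by the Methanobacterium formicicum (GenBank JADIIL000000000) and
# Methanobrevibacter arboriphilus (GenBank JADIIN000000000) genome bins
# from the TCE/Cr(VI) biocathode. Gene content follows the deposited
# annotations; locus identifiers are synthetic placeholders (the source
# table prints gene symbols and functions only).
locus_id	gene	product
MGEN0001	fwdA	Formylmethanofuran dehydrogenase subunit A
MGEN0002	fwdB	Formylmethanofuran dehydrogenase subunit B
MGEN0003	fwdC	Formylmethanofuran dehydrogenase subunit C
MGEN0004	fwdD	Formylmethanofuran dehydrogenase subunit D
MGEN0005	fdhD	Formate dehydrogenase accessory protein FdhD
MGEN0006	fdhF	Formate dehydrogenase H
MGEN0007	mob	Molybdopterin-guanine dinucleotide biosynthesis protein B
MGEN0008	ftr	Formylmethanofuran--tetrahydromethanopterin N-formyltransferase
MGEN0009	fhcD	Formylmethanofuran--tetrahydromethanopterin N-formyltransferase subunit D
MGEN0010	mch	Methenyltetrahydromethanopterin cyclohydrolase
MGEN0011	mer	5,10-methylenetetrahydromethanopterin reductase
MGEN0012	mtd	F420-dependent methylenetetrahydromethanopterin dehydrogenase
MGEN0013	mcrA	Coenzyme-B sulfoethylthiotransferase subunit alpha
MGEN0014	mcrB	Coenzyme-B sulfoethylthiotransferase subunit beta
MGEN0015	mcrG	Coenzyme-B sulfoethylthiotransferase subunit gamma
MGEN0016	mcrC	Methyl-coenzyme M reductase I operon protein C
MGEN0017	mcrD1	Methyl-coenzyme M reductase I operon protein D1
MGEN0018	mcrD2	Methyl-coenzyme M reductase I operon protein D2
MGEN0019	mtrA	Tetrahydromethanopterin S-methyltransferase subunit A
MGEN0020	mtrC	Tetrahydromethanopterin S-methyltransferase subunit C
MGEN0021	mtrD	Tetrahydromethanopterin S-methyltransferase subunit D
MGEN0022	mtrE	Tetrahydromethanopterin S-methyltransferase subunit E
MGEN0023	mtrF	Tetrahydromethanopterin S-methyltransferase subunit F
MGEN0024	mtrG	Tetrahydromethanopterin S-methyltransferase subunit G
MGEN0025	mtrH	Tetrahydromethanopterin S-methyltransferase subunit H
MGEN0026	frhA	Coenzyme F420 hydrogenase subunit alpha
MGEN0027	frhB	Coenzyme F420 hydrogenase subunit beta
MGEN0028	frhG	Coenzyme F420 hydrogenase subunit gamma
MGEN0029	frhD	Coenzyme F420-reducing hydrogenase FrhD
MGEN0030	mvhA	F420-non-reducing hydrogenase subunit A
MGEN0031	mvhG	F420-non-reducing hydrogenase subunit G
MGEN0032	hdrB	CoB-CoM heterodisulfide reductase subunit B
MGEN0033	hdrC	CoB-CoM heterodisulfide reductase subunit C
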