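# Hydrogenase genes of the D. mccartyi genome bin from the TCE/Cr(VI)
# biocathode (GenBank JADIIK000000000). Complexes represented: Hyp, Hyc,
# Hym, Vhu, Ech; no H2-uptake (hup) genes are present.
locus_id	gene	product
MBF4481889	hypA	Hydrogenase maturation nickel metallochaperone HypA
MBF4481888	hypB	Hydrogenase nickel incorporation protein HypB
MBF4481885	hypD	Hydrogenase formation protein HypD
MBF4481884	hypE	Hydrogenase expression/formation protein HypE
MBF4481887	hypF	Hydrogenase maturation factor HypF
MBF4483122	hyaD/hybD	HyaD/HybD family hydrogenase maturation endopeptidase
MBF4482458	hycC	Hydrogenase membrane subunit
MBF4481886	hypC/hybG/hupF	HypC/HybG/HupF family hydrogenase formation chaperone
MBF4483158	hymD	[Fe] hydrogenase, HymD subunit
MBF4483157	hymC	[Fe] hydrogenase, small subunit
MBF4482774	vhuA	Ni/Fe hydrogenase subunit alpha
MBF4482773	vhuG	Methyl viologen-reducing hydrogenase VhuG
MBF4482967	echE	Ni-dependent hydrogenase large subunit
MBF4482820	cdhC	CO dehydrogenase/CO-methylating acetyl-CoA synthase complex subunit beta
MBF4482137	frhB	Coenzyme F420 hydrogenase/dehydrogenase, beta subunit C-terminal domain
MBF4483124		Ni/Fe hydrogenase small subunit hydrogenase
MBF4482460		Hydrogenase-4 component E
MBF4482775		Hydrogenase maturation protease
MBF4482461		Hydrogenase membrane subunit
MBF4483123		Ni-dependent hydrogenase large subunit
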