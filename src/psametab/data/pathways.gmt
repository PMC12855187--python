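glucose-alanine cycle	Muscle-liver nitrogen/glucose shuttle	glucose	alanine	glutamate	glutamine	pyruvate	alpha-ketoglutarate	lactate
glycine and serine metabolism	Glycine, serine and threonine metabolism	serine	glycine	threonine	tryptophan	methionine	cysteine	pyruvate	glutamate	choline	betaine
glutathione metabolism	Glutathione synthesis and redox cycling	glutathione	glutamate	cysteine	glycine	glutamine	5-oxoproline	alanine
selenoamino acid metabolism	Selenocysteine and selenomethionine pathways	selenomethionine	selenocysteine	methionine	serine	cysteine	glutathione	alanine
alanine metabolism	Alanine synthesis and degradation	alanine	pyruvate	glutamate	alpha-ketoglutarate	glutamine
tryptophan metabolism	Kynurenine and serotonin branches	tryptophan	kynurenine	serotonin	alanine	indoleacetate	quinolinate
valine leucine and isoleucine degradation	Branched-chain amino acid catabolism	valine	leucine	isoleucine	alpha-ketoglutarate	glutamate	acetoacetate	succinate
methionine metabolism	Methionine cycle and transsulfuration	methionine	homocysteine	cysteine	serine	glycine	s-adenosylmethionine
glutamate metabolism	Glutamate-glutamine interconversion	glutamate	glutamine	alpha-ketoglutarate	alanine	aspartate	gaba
urea cycle	Ammonia detoxification	arginine	ornithine	citrulline	aspartate	urea	glutamate
gluconeogenesis	De novo glucose synthesis	glucose	pyruvate	lactate	alanine	oxaloacetate	glycerol
glycolysis	Glucose catabolism to pyruvate	glucose	pyruvate	lactate	fructose-6-phosphate	phosphoenolpyruvate
aspartate metabolism	Aspartate synthesis and degradation	aspartate	asparagine	oxaloacetate	glutamate	arginine
phenylalanine and tyrosine metabolism	Aromatic amino acid catabolism	phenylalanine	tyrosine	fumarate	acetoacetate
arginine and proline metabolism	Arginine, ornithine and proline pathways	arginine	proline	ornithine	glutamate	glycylproline	creatine
beta-alanine metabolism	Beta-alanine and histidine dipeptides	beta-alanine	anserine	carnosine	histidine	aspartate
taurine and hypotaurine metabolism	Taurine synthesis from cysteine	taurine	hypotaurine	cysteine	methionine
cysteine metabolism	Cysteine synthesis and catabolism	cysteine	serine	methionine	taurine	pyruvate	glutathione	2-aminobutyrate
purine metabolism	Purine nucleotide turnover	hypoxanthine	xanthine	urate	inosine	adenine	glutamine	glycine
ketone body metabolism	Ketogenesis and ketolysis	acetoacetate	3-hydroxybutyrate	acetone	acetyl-coa
ascorbate and aldarate metabolism	Vitamin C and sugar acid pathways	ascorbate	threonate	glucose	glucuronate
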