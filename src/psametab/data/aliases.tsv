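alias	canonical
l-alanine	alanine
l-leucine	leucine
l-isoleucine	isoleucine
l-valine	valine
l-serine	serine
l-methionine	methionine
l-glutamine	glutamine
l-glutamate	glutamate
l-glutamic acid	glutamate
glutamic acid	glutamate
l-tryptophan	tryptophan
l-cysteine	cysteine
l-glycine	glycine
d-glucose	glucose
glycyl-proline	glycylproline
glycyl proline	glycylproline
glycilproline	glycylproline
2-aminobutyric acid	2-aminobutyrate
alpha-aminobutyrate	2-aminobutyrate
threonic acid	threonate
l-threonine	threonine
l-aspartate	aspartate
aspartic acid	aspartate
l-arginine	arginine
l-proline	proline
l-phenylalanine	phenylalanine
l-tyrosine	tyrosine
lactic acid	lactate
pyruvic acid	pyruvate
uric acid	urate
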