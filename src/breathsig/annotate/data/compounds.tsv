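compound	formula	pathways
Glutarate	C5H8O4	lysine degradation;fatty acid metabolites
Succinate	C4H6O4	lysine degradation;fatty acid metabolites
2-Hydroxyglutarate	C5H8O5	lysine degradation;fatty acid metabolites
Glutaconate	C5H6O4	lysine degradation;fatty acid metabolites
2-Oxoadipate	C6H8O5	lysine degradation;2-oxocarboxylic acid metabolism;fatty acid metabolites
2-Aminoadipate	C6H11NO4	lysine degradation;2-oxocarboxylic acid metabolism;fatty acid metabolites
Glutarate semialdehyde	C5H8O3	lysine degradation;fatty acid metabolites
5,6-Dihydroxyindole-2-carboxylate	C9H7NO4	tyrosine metabolism
Succinylacetone	C7H10O4	tyrosine metabolism
Succinylacetoacetate	C8H10O6	tyrosine metabolism
3,4-Dihydroxyphenylpyruvate	C9H8O5	tyrosine metabolism
4-Hydroxyphenyllactate	C9H10O4	tyrosine metabolism
4-Coumarate	C9H8O3	tyrosine metabolism
3,4-Dihydroxymandelaldehyde	C8H8O4	tyrosine metabolism
4-Hydroxyphenylpyruvate	C9H8O4	tyrosine metabolism
3-Methoxy-4-hydroxymandelate	C9H10O5	tyrosine metabolism
4-Maleylacetoacetate	C8H8O6	tyrosine metabolism
Homogentisate	C8H8O4	tyrosine metabolism
2-Oxosuberate	C8H12O5	2-oxocarboxylic acid metabolism
cis-(Homo)3-aconitate	C9H12O6	2-oxocarboxylic acid metabolism
3-Isopropylmalate	C7H12O5	2-oxocarboxylic acid metabolism
Glutamate	C5H9NO4	2-oxocarboxylic acid metabolism
2-Aceto-2-hydroxybutanoate	C6H10O4	2-oxocarboxylic acid metabolism
Adipate	C6H10O4	fatty acid metabolites
Hexenedioate	C6H8O4	fatty acid metabolites
Heptenedioate	C7H10O4	fatty acid metabolites
omega-Oxoheptanoate	C7H12O3	fatty acid metabolites
omega-Oxopentenoate	C5H8O4	fatty acid metabolites
omega-Oxooctenoate	C8H12O3	fatty acid metabolites
omega-Oxononadienoate	C9H12O3	fatty acid metabolites
omega-Oxodecadienoate	C10H14O3	fatty acid metabolites
Butanoate	C4H8O2	fatty acid metabolites
Pentanoate	C5H10O2	fatty acid metabolites
2,7-Dimethyl-2,4-octadienedioate	C10H14O4	fatty acid metabolites
2-Amino-3,4-dihydroxypentanedioate	C5H9NO6	fatty acid metabolites
2,3-Dihydroxypentanoate	C5H10O4	fatty acid metabolites
2-Dehydro-xylonate	C5H8O6	monosaccharides and metabolites
Arabinose	C5H10O5	monosaccharides and metabolites
Galactose	C6H12O6	monosaccharides and metabolites
Glucuronate	C6H10O7	monosaccharides and metabolites
Glucarate	C6H10O8	monosaccharides and metabolites
Glycerol	C3H8O3	monosaccharides and metabolites
Erythrulose	C4H8O4	monosaccharides and metabolites
4-Aminobutanoate	C4H9NO2	arginine and proline metabolism
4-Aminobutanal	C4H9NO	arginine and proline metabolism
Proline	C5H9NO2	arginine and proline metabolism;arginine biosynthesis
Ornithine	C5H12N2O2	arginine and proline metabolism;arginine biosynthesis
Arginine	C6H14N4O2	arginine and proline metabolism;arginine biosynthesis
4-Acetamidobutanoate	C6H11NO3	arginine and proline metabolism
1-Pyrroline-2-carboxylate	C5H7NO2	arginine and proline metabolism
Hydroxyproline	C5H9NO3	arginine and proline metabolism
Glutamate 5-semialdehyde	C5H9NO3	arginine and proline metabolism
N4-Acetylaminobutanal	C6H11NO2	arginine and proline metabolism
4-Hydroxyglutamate semialdehyde	C5H9NO4	arginine and proline metabolism;arginine biosynthesis
1-Pyrroline-3-hydroxy-5-carboxylate	C5H7NO3	arginine and proline metabolism;arginine biosynthesis
Urea	CH4N2O	arginine biosynthesis
Fumarate	C4H4O4	arginine biosynthesis
Maleate	C4H4O4	arginine biosynthesis
Linoleate	C18H32O2	linoleic acid metabolism
13(S)-HPODE	C18H32O4	linoleic acid metabolism
13(S)-HODE	C18H32O3	linoleic acid metabolism
4-Hydroxy-2-hexenal	C6H10O2	aldehydes
4-Hydroxy-2-heptenal	C7H12O2	aldehydes
4-Hydroxy-2-octenal	C8H14O2	aldehydes
4-Hydroxy-2-pentadecenal	C15H28O2	aldehydes
4-Hydroxy-2,6-octadienal	C8H12O2	aldehydes
4-Hydroxy-2,6-nonadienal	C9H14O2	aldehydes
4-Hydroxy-2,6-tridecadienal	C13H22O2	aldehydes
4-Hydroxy-2,6-pentadecadienal	C15H26O2	aldehydes
4-Hydroxy-2,6-hexadecadienal	C16H28O2	aldehydes
Dodecanamide	C12H25NO	fatty amides
Hexadecanamide	C16H33NO	fatty amides
Octadecanamide	C18H37NO	fatty amides
N,N-bis(2-hydroxyethyl)dodecanamide	C16H33NO3	fatty amides
Palmitoleoylethanolamide	C18H35NO2	fatty amides
Palmitoylethanolamide	C18H37NO2	fatty amides
10,16-Dihydroxyhexadecanoate	C16H32O4	fatty acids
11-Aminoundecanoate	C11H23NO2	fatty acids
6-Hydroxyhexanoate	C6H12O3	fatty acids
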