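mirna	predicted_function	expectation	location	inhibition	target_genes	manual
mcr-miR156	Squamosa promoter-binding protein-like (SPL)	0	ORF	Cleavage	tr_25478;92930;247074;130241;134702;242974	no
mcr-miR156	Glutaredoxin family protein	2.5	ORF	Cleavage	tr_222987	no
mcr-miR156	NAD(P)-binding Rossmann-fold superfamily protein	3	ORF	Cleavage	tr_112639;112626	no
mcr-miR156	Oxophytodienoate-reductase 3	3	ORF	Cleavage	tr_8553	no
mcr-miR156	Tetratricopeptide repeat-like superfamily protein	3	ORF	Cleavage	tr_211611	no
mcr-miR156	NAD(P)-dehydrogenase	3	ORF	Cleavage	tr_20823	no
mcr-miR156	F-box family protein	3	ORF	Translation	tr_250578	no
mcr-miR156	Gibberellin receptor GID1B	3	5' UTR	Translation	tr_131891	no
mcr-miR159	MYB domain protein 33	2.5	ORF	Cleavage	tr_247776	no
mcr-miR159	Cytidinediphosphate diacylglycerol synthase 2	2.5	5' UTR	Cleavage	tr_24710	no
mcr-miR159	Polyketide cyclase/dehydrase lipid transport protein	3	ORF	Cleavage	tr_247457	no
mcr-miR159	Histone H2A protein 9	3	ORF	Cleavage	tr_31155	no
mcr-miR159	ATP binding cassette subfamily B1	3	ORF	Cleavage	tr_75146	no
mcr-miR159	RNA ligase	3	ORF	Cleavage	tr_251381	no
mcr-miR159	Glycosylhydrolase superfamily protein	3	ORF	Cleavage	tr_63329	no
mcr-miR160	Auxin response factor (ARF) 16	0.5	ORF	Cleavage	tr_131045	no
mcr-miR160	Glutathione-regulated potassium-efflux protein	2.5	ORF	Cleavage	tr_29190	no
mcr-miR162	Dicer like-1	2	ORF	Cleavage	tr_87681	no
mcr-miR162	Pyridoxamine 5'-phosphate oxidase family protein	3	ORF	Translation	tr_128506	no
mcr-miR164	NAC domain containing protein	1	ORF	Cleavage	tr_20281	no
mcr-miR166	Homeobox-leucine zipper family protein (HD-ZIP)	1.5	ORF	Cleavage	tr_23906;16028	no
mcr-miR166	NB-ARC domain-containing disease resistance protein	3	ORF	Translation	tr_6344	no
mcr-miR168	Argonuate 1	3.5	ORF	Cleavage	tr_23616	no
mcr-miR168	Cytochrome P450, family 76	3	ORF	Translation	tr_34562;106564	no
mcr-miR169	Nuclear factor Y subunit A (NF-YA)	2	3' UTR	Cleavage	tr_241835	no
mcr-miR169	Haloacid dehydrogenase	3	ORF	Cleavage	tr_78265	no
mcr-miR171	Scarecrow-like protein (SCL) 6	0.5	ORF	Cleavage	tr_129576	no
mcr-miR171	Early-responsive to dehydration stress protein (ERD4)	3	ORF	Cleavage	tr_88429	no
mcr-miR171	Cysteine-rich RLK (Receptor-like protein kinase) 25	3	ORF	Cleavage	tr_72609	no
mcr-miR171	Subtilisin-like serine protease 3	3	ORF	Cleavage	tr_23970	no
mcr-miR171	ARM repeat superfamily protein	3	ORF	Cleavage	tr_25709	no
mcr-miR319	MYB domain protein 33	2.5	ORF	Cleavage	tr_247776	no
mcr-miR319	TCP-4 transcription factor	4	ORF	Cleavage	tr_248183	yes
mcr-miR396	Growth-regulating factor (GRF) 2	2	ORF	Cleavage	tr_20229	no
mcr-miR396	Alfin-like 3	2.5	ORF	Cleavage	tr_86713	no
mcr-miR396	Heat shock protein 81.4	3	ORF	Translation	tr_24595	no
mcr-miR396	Ribosomal protein L1p/L10e family	3	ORF	Cleavage	tr_27243	no
mcr-miR396	Zinc finger protein-related	3	ORF	Cleavage	tr_8491	no
mcr-miR396	F-box protein	3	3' UTR	Cleavage	tr_24495	no
mcr-miR396	Proteasome family protein	3	3' UTR	Translation	tr_25619	no
mcr-miR403	Argonaute 2	1	3' UTR	Cleavage	tr_81134	no
mcr-miR403	Ubiquitin-specific protease	3	3' UTR	Translation	tr_23630	no
mcr-miR403	ADP-ribosylation factor GTPase-activating protein	3	ORF	Translation	tr_25728	no
mcr-miR1	Mitochondrial transcription termination factor protein	1.5	ORF	Cleavage	tr_26362;27606	no
mcr-miR1	Germin-like protein	3	ORF	Cleavage	tr_140178	no
mcr-miR1	Thioredoxin superfamily protein	3	ORF	Cleavage	tr_126594	no
mcr-miR1	Ubiquitin-specific protease	3	ORF	Cleavage	tr_90873	no
mcr-miR1	BED zinc finger; hAT family dimerisation domain	3	ORF	Translation	tr_16919	no
mcr-miR3	Sodium/myo-inositol symporter (ITR) 3	3	ORF	Cleavage	tr_16378	no
mcr-miR3	Cytochrome P450, family 81	3	ORF	Translation	tr_127844	no
mcr-miR4	Leucine-rich repeat transmembrane protein kinase	0.5	3' UTR	Cleavage	tr_124137	no
mcr-miR4	Multi-antimicrobial extrusion (MATE) efflux protein	0.5	3' UTR	Cleavage	tr_15134	no
mcr-miR4	Protein translocase subunit SecA, chloroplastic	1.5	3' UTR	Cleavage	tr_77781	no
mcr-miR4	Protein kinase superfamily protein	1.5	3' UTR	Cleavage	tr_91240;91241;91239	no
mcr-miR4	NAD(P)-binding Rossmann-fold superfamily protein	3	ORF	Cleavage	tr_28492	no
mcr-miR5	Phosphofructokinase 3 (PFK)	2	ORF	Cleavage	tr_24929	no
mcr-miR5	Tetratricopeptide repeat-like superfamily protein	2	ORF	Cleavage	tr_251318	no
mcr-miR10	Germin 3	3	3' UTR	Cleavage	tr_32811	no
mcr-miR11	Ribosomal protein L34	2.5	ORF	Cleavage	tr_32249	no
mcr-miR12	Arginyl-tRNA synthetase	3	ORF	Translation	tr_249031	no
mcr-miR12	Translin family protein	3	ORF	Cleavage	tr_131509	no
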