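# Screening assay catalogue: 32 TaqMan qPCR methods of the routine GMO feed screening set.
# Columns: name, category (endogenous|element|construct|virus), crop_scope (endogenous only;
# "all-plants" for the general plant actin control), forward/reverse primer and probe
# sequences (5'-3', IUPAC; probes carry FAM/TAMRA labels not shown), final primer and probe
# concentrations in nM, and a literature reference key.
name	category	crop_scope	fwd	rev	probe	primer_nM	probe_nM	reference
Plant actin	endogenous	all-plants	CAAGCAGCATGAAGATCAAGGT	CACATCTGTTGGAAAGTGCTGAG	CCTCCAATCCAGACACTGTACTTYCTCTC	400	200	CR27
Canola FatA	endogenous	canola	GGTCTCTCAGCAAGTGGGTGAT	TCGTCCCGAACTTCATCTGTAA	ATGAACCAAGACACAAGGCGGCTTCA	400	200	CR28
Maize HMG	endogenous	maize	TTGGACTAGAAATCTCGTGCTGA	GCTACATAGGGAGCCTTGTCCT	CAATCCACACAAACGCACGCGTA	400	200	CR28
Rice SPS	endogenous	rice	TTGCGCCTGAACGGATAT	CGGTTGATCTTTTCGGGATG	TCCGAGCCGTCCGTGCGTC	400	200	CR29
Soy Lec	endogenous	soy	CCAGCTTCGCCGCTTCCTTC	GAAGGCAAGCCCATCTGCAAGCC	CTTCACCTTCTATGCCCCTGACAC	400	200	CR28
Sugar beet GS	endogenous	sugar beet	GACCTCCATATTACTGAAAGGAAG	GAGTAATTGCTCCATCCTGTTCA	CTACGAAGTTTAAAGTATGTGCCGCTC	400	200	CR28
Wheat Wx-1	endogenous	wheat	GTCGCGGGAACAGAGGTGT	GGTGTTCCTCCATTGCGAAA	CAAGGCGGCCGAAATAAGTTGCC	400	200	CR30
P-35S	element		ATTGATGTGATATCTCCACTGACGT	CCTCTCCAAATGAAATGAACTTCCT	CCCACTATCCTTCGCAAGACCCTTCCT	400	200	CR26
P-FMV	element		CGAAGACTTAAAGTTAGTGGGCATCT	TTTTGTCTGGTCCCCACAA	TGAAAGTAATCTTGTCAACATCGAGCAGCTGG	340	540	CR17
P-nos	element		GTGACCTTAGGCGACTTTTGAAC	CGCGGGTTTCTGGAGTTTAA	CGCAATAATGGTTTCTGACGTATGTGCTTAGC	340	540	CR17
P-Rice actin	element		TCGAGGTCATTCATATGCTTGAG	TTTTAACTGATGTTTTCACTTTTGACC	AGAGAGTCGGGATAGTCCAAAATAAAACAAAGGTA	340	540	CR17
P-SSuAra	element		GGCCTAAGGAGAGGTGTTGAGA	CTCATAGATAACGATAAGATTCATGGAATT	CCTTATCGGCTTGAACCGCTGGAATAA	340	540	CR17
T-35S	element		AGGGTTTCTTATATGCTCAACACATG	TCACCAGTCTCTCTCTACAAATCTATCAC	AAACCCTATAAGAACCCTAATTCCCTTATCTGGGA	340	540	CR17
T-E9	element		TGAGAATGAACAAAAGGACCATATCA	TTTTTATTCGGTTTTCGCTATCG	TCATTAACTCTTCTCCATCCATTTCCATTTCACAGT	340	540	CR17
T-g7 (T-ORF1)	element		ATGCAAGTTTAAATTCAGAAATATTTCAA	ATGTATTACACATAATATCGCACTCAGTCT	ACTGATTATATCAGCTGGTACATTGCCGTAGATGA	340	540	CR17
T-nos	element		GTCTTGCGATGATTATCATATAATTTCTG	CGCTATATTTTGTTTTCTATCGCGT	AGATGGGTTTTTATGATTAGAGTCCCGCAA	400	200	CR26
CP4-epsps	element		GCCTCGTGTCGGAAAACCCT	TTCGTATCGGAGAGTTCGATCTTC	TGCCACGATGATCGCCACGAGCTTCC	400	200	CR23
Cry1A(b)	element		GGACAACAACCCMAACATCAAC	GCACGAACTCGCTSAGCAG	CATCCCGTACAACTGCCTCAGCAACCCTG	400	200	CR23
Cry1A.105	element		TCAGAGGTCCAGGGTTTACAGG	GTAGTAGAGGCATAGCGGATTCTTG	AGACATTCTTCGTCGCACAAGTGGAGGACC	400	200	CR18
Cry1Ab/Ac	element		GAGGAAATGCGTATTCAATTCAAC	TTCTGGACTGCGAACAATGG	ACATGAACAGCGCCTTGACCACAGC	400	200	CR31
Cry1F	element		GACGTGGATCTTCATCTGCAATC	GCAACACGGCTGGCAATCG	CGCCCCCGGGATTGAAGACCCCGTAAC	400	200	CR23
Cry2Ab2	element		AATTCTAACTACTTCCCCGACTACTTC	ACGGAGAGGCGATGTTCCTG	TCTCTGGTGTTCCTCTCGTCGTCCGCA	400	200	CR18
Cry3Bb1	element		CCGCCCAGGACTCCATCG	GAGGCACCCGAGGACAGG	CTGCCGCCTGAGACCACTGACGAGC	400	200	CR23
Vip3A	element		TCACCAAGAAGATGAAGAC	CTCTCCACCTTCTTCTTG	TGACCGCCAACTTCTACGACA	400	200	CR8
bar	element		ACTGGGCTCCACGCTCTACA	AAACCCACGTCATGCCAGTTC	ATGCTGCGGGCGGCCGGCTTCAAGCACGG	400	200	CR32
pat	element		GACAGAGCCACAAACACCACAA	CAATCGTAAGCGTTCCTAGCCT	GCCACAACACCCTCAACCTCA	400	200	CR5
nptII	element		GACAGGTCGGTCTTGACAAAAAG	GAACAAGATGGATTGCACGC	TGCCCAGTCATAGCCGAATAGCCTCTCCA	400	200	CR23
I-rAct1	element		TCGTCAGGCTTAGATGTGCTAGA	CTGCATTTGTCACAAATCATGAA	TTTGTGGGTAGAATTTGAATCCCTCAGC	400	200	CR32
Barstar	element		AACAAATCAGAAGTATCAGCGACCT	AACTGCCTCCATTCCAAAACG	ACCTGGACGCTTTATGGGATT	400	200	CR5
CaMV	virus		TGAAATCCTCAGTGACCAAAAATC	TACAAGGACAATCATTGATGAGC	AAGCCGTTGCAGCGAAAATCGTTAATGA	300	200	CR33
ctp2/CP4-epsps	construct		GGGATGACGTTAATTGGCTCTG	GGCTGCTTGCACCGTGAAG	CACGCCGTGGAAACAGAAGACATGACC	375	150	CR34
ctp4/CP4-epsps	construct		CCTTTAGGATTTCAGCATCAGTGG	GACTTGTCGCCGGGAATG	CGCAACCGCCCGCAAATCC	500	200	CR26
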