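# Distribution of the 32 screening methods over eight 96-well plates, four mixes per plate.
plate	mix	assay
1	1	Plant actin
1	2	Canola FatA
1	3	Maize HMG
1	4	Rice SPS
2	1	Soy Lec
2	2	Sugar beet GS
2	3	Wheat Wx-1
2	4	P-35S
3	1	P-FMV
3	2	P-nos
3	3	P-SSuAra
3	4	T-35S
4	1	T-E9
4	2	T-g7 (T-ORF1)
4	3	T-nos
4	4	CP4-epsps
5	1	Cry1A(b)
5	2	Cry1A.105
5	3	Cry1Ab/Ac
5	4	Cry1F
6	1	Cry2Ab2
6	2	Cry3Bb1
6	3	Vip3A
6	4	bar
7	1	pat
7	2	nptII
7	3	I-rAct1
7	4	Barstar
8	1	CaMV
8	2	ctp2/CP4-epsps
8	3	ctp4/CP4-epsps
8	4	P-Rice actin
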