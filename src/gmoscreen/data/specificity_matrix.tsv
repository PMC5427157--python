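# Specificity matrix of the 25 non-endogenous screening methods against 60 GMO events,
# transcribed from the published specificity table of the routine screening strategy.
# Cell symbols: +  detected; -  tested, not detected; X  contains the element but it is
# not detected because of sequence differences; +*  detected, likely through sequence
# similarity of the target (real signal, cross-reaction); (+)  expected positive but not
# verified experimentally (no reference material); empty  expected negative, not verified.
# Transcription provenance: the machine-extracted rendering of the published table is
# misaligned; rows were reconstructed from the table fragments cross-checked against the
# positive-control assignments and the prose (worked MON89034/MON810 example, the seven
# zero-coverage events, DP356043/MON87460 sequence-divergence notes, T45/DAS59122 T-35S
# positives, Bt11 T-35S +*, the MON1445/MON531/MON88302 cross-contamination account).
# Cells that could not be recovered unambiguously are encoded with the unverified states.
# Authorisation statuses are configuration, not measurement: every event defaults to
# "unknown" except DAS59132 (E32), which the source text itself calls unauthorised.
# Statuses may be edited; allowed values: authorised, low_level_619_2011, expired,
# unauthorised, unknown.
event	crop	status	P-35S	P-FMV	P-nos	P-Rice actin	P-SSuAra	T-35S	T-E9	T-g7 (T-ORF1)	T-nos	CP4-epsps	Cry1A(b)	Cry1A.105	Cry1Ab/Ac	Cry1F	Cry2Ab2	Cry3Bb1	Vip3A	bar	pat	nptII	I-rAct1	Barstar	CaMV	ctp2/CP4-epsps	ctp4/CP4-epsps
A2704-12 soy	soy	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
A5547-127 soy	soy	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
CV127 soy	soy	unknown	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
DAS44406 soy	soy	unknown	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
DAS68416 soy	soy	unknown	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
DAS81419 soy	soy	unknown	-	-	-	-	-	-	-	-	-	-	-	-	+	+	-	-	-	-	+	-	-	-	-	-	-
DP305423 soy	soy	unknown	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
DP356043 soy	soy	unknown	X	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
FG72 soy	soy	unknown	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
GTS 40-3-2 soy	soy	unknown	+	-	-	-	-	-	-	-	+	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+
MON87701 soy	soy	unknown	-	-	-	-	+	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-
MON87705 soy	soy	unknown	-	+	-	-	-	-	+	-	-	X	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
MON87708 soy	soy	unknown	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
MON87769 soy	soy	unknown	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
MON89788 soy	soy	unknown	-	+	-	-	-	-	+	-	-	X	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
3272 maize	maize	unknown	-	-	-	-	-	X	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
5307 maize	maize	unknown	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	X	-	-	-	-	-	-	-	-	-
Bt11 maize	maize	unknown	+	-	-	-	-	+*	-	-	+	-	X	-	+	-	-	-	-	-	+	-	-	-	-	-	-
Bt176 maize	maize	unknown	+	-	-	-	-	X	-	-	-	-	+	-	X	-	-	-	-	+	-	-	-	-	-	-	-
CBH351 maize	maize	unknown	+	-	-	-	-	-	-	-	(+)	-	-	-	-	-	-	-	-	+	-	+	-	-	-	-	-
DAS40278 maize	maize	unknown	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
DAS59122 maize	maize	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
DAS59132 (E32) maize	maize	unauthorised	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	+	-	-	-	-	-	-
DP98140 maize	maize	unknown	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
GA21 maize	maize	unknown	-	-	-	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-
MIR162 maize	maize	unknown	-	-	-	-	-	X	-	-	+	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-
MIR604 maize	maize	unknown	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
MON810 maize	maize	unknown	+	-	-	-	-	-	-	-	-	-	+	-	X	-	-	-	-	-	-	-	-	-	-	-	-
MON863 maize	maize	unknown	+	-	-	-	-	-	-	-	+	-	-	-	-	-	-	+	-	-	-	+	+	-	-	-	-
MON87427 maize	maize	unknown	+	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
MON87460 maize	maize	unknown	+	-	-	X	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	+	+	-	-	-	-
MON88017 maize	maize	unknown	+	-	-	+	-	-	-	-	+	+	-	-	-	-	-	+	-	-	-	-	+	-	-	+	-
MON89034 maize	maize	unknown	+	+	-	-	-	-	-	-	+	-	+	+	X	-	+	-	-	-	-	-	+	-	-	-	-
NK603 maize	maize	unknown	+	-	-	+	-	-	-	-	+	+	-	-	-	-	-	-	-	-	-	-	+	-	-	+	-
T25 maize	maize	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
TC1507 maize	maize	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	+	-	-	-	-	+	-	-	-	-	-	-
DP073496 canola	canola	unknown	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
MON88302 canola	canola	unknown	-	+	-	-	-	-	+	-	-	X	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
Ms1 canola	canola	unknown	-	-	+	-	+	-	-	+	+	-	-	-	-	-	-	-	-	+	-	+	-	-	-	-	-
Ms8 canola	canola	unknown	-	-	-	-	+	-	-	+	+	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-
Rf1 canola	canola	unknown	-	-	+	-	+	-	-	+	+	-	-	-	-	-	-	-	-	+	-	+	-	+	-	-	-
Rf2 canola	canola	unknown	-	-	+	-	+	-	-	+	+	-	-	-	-	-	-	-	-	+	-	+	-	+	-	-	-
Rf3 canola	canola	unknown	-	-	-	-	+	-	-	+	+	-	-	-	-	-	-	-	-	+	-	-	-	+	-	-	-
GT73 canola	canola	unknown	-	+	-	-	-	-	+	-	-	X	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
T45 canola	canola	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-
TOPAS 19/2 canola	canola	unknown	+	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	+	+	-	-	-	-	-
EH92-527-1 potato	potato	unknown	-	-	+	-	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-
281-24-236x3006-210-23 cotton	cotton	unknown	-	-	-	-	-	-	-	-	-	-	-	-	X	+	-	-	-	-	+	-	-	-	-	-	-
GHB119 cotton	cotton	unknown	+	-	-	-	-	+	-	-	+	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-
GHB614 cotton	cotton	unknown	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-
LL25 cotton	cotton	unknown	+	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-
MON1445 cotton	cotton	unknown	+	+	-	-	-	-	+	-	+	+	-	-	-	-	-	-	-	-	-	+	-	-	-	+	-
MON15985 cotton	cotton	unknown	+	-	-	-	-	-	-	-	+	-	-	-	+	-	+	-	-	-	-	+	-	-	-	-	-
MON531 cotton	cotton	unknown	+	-	-	-	-	-	-	-	+	-	-	-	+	-	-	-	-	-	-	+	-	-	-	-	-
MON88913 cotton	cotton	unknown	+	+	-	-	-	-	-	-	-	X	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
T304-40 cotton	cotton	unknown	+	-	-	-	-	-	-	-	-	-	+	-	+	-	-	-	-	+	-	-	-	-	-	-	-
Bt63 rice construct	rice	unknown				(+)					+				+							+	(+)				
LL601 rice	rice	unknown	+	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-
LL62 rice	rice	unknown	+	-	-	-	-	+	-	-	-	-	-	-	-	-	-	-	-	+	-	-	-	-	-	-	-
H7-1 sugar beet	sugar beet	unknown	-	+	-	-	-	-	+	-	-	X	-	-	-	-	-	-	-	-	-	-	-	-	-	+	-
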