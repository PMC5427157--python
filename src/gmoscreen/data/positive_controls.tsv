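# Positive sensitivity control material per screening method (one control well per assay per
# run, at the 0.1%-GMO / 25-copy level). kind: event_crm = certified GMO reference material
# of the named event; non_gmo_crop = non-modified plant material (drives endogenous assays
# only); virus = CaMV-positive sample.
# Note: the source protocol lists MON810 maize as control for CP4-epsps and ctp4/CP4-epsps,
# but MON810 carries neither target; GTS 40-3-2 soy (which carries both) is assigned here.
assay	material	kind	event	crop
Plant actin	A2704-12 soy CRM	event_crm	A2704-12 soy	soy
Canola FatA	non-GMO canola AOCS0306B	non_gmo_crop		canola
Maize HMG	MIR162 maize CRM	event_crm	MIR162 maize	maize
Rice SPS	non-GMO rice AOCS0306D	non_gmo_crop		rice
Soy Lec	DP305423 soy CRM	event_crm	DP305423 soy	soy
Sugar beet GS	H7-1 sugar beet CRM	event_crm	H7-1 sugar beet	sugar beet
Wheat Wx-1	common wheat	non_gmo_crop		wheat
P-35S	MON810 maize CRM	event_crm	MON810 maize	maize
P-FMV	MON89788 soy CRM	event_crm	MON89788 soy	soy
P-nos	Rf1 canola CRM	event_crm	Rf1 canola	canola
P-Rice actin	NK603 maize CRM	event_crm	NK603 maize	maize
P-SSuAra	MON87701 soy CRM	event_crm	MON87701 soy	soy
T-35S	TC1507 maize CRM	event_crm	TC1507 maize	maize
T-E9	MON89788 soy CRM	event_crm	MON89788 soy	soy
T-g7 (T-ORF1)	Rf1 canola CRM	event_crm	Rf1 canola	canola
T-nos	NK603 maize CRM	event_crm	NK603 maize	maize
CP4-epsps	GTS 40-3-2 soy CRM	event_crm	GTS 40-3-2 soy	soy
Cry1A(b)	MON810 maize CRM	event_crm	MON810 maize	maize
Cry1A.105	MON89034 maize CRM	event_crm	MON89034 maize	maize
Cry1Ab/Ac	MON87701 soy CRM	event_crm	MON87701 soy	soy
Cry1F	TC1507 maize CRM	event_crm	TC1507 maize	maize
Cry2Ab2	MON89034 maize CRM	event_crm	MON89034 maize	maize
Cry3Bb1	MON863 maize CRM	event_crm	MON863 maize	maize
Vip3A	MIR162 maize CRM	event_crm	MIR162 maize	maize
bar	Rf1 canola CRM	event_crm	Rf1 canola	canola
pat	TC1507 maize CRM	event_crm	TC1507 maize	maize
nptII	MON863 maize CRM	event_crm	MON863 maize	maize
I-rAct1	MON863 maize CRM	event_crm	MON863 maize	maize
Barstar	Rf1 canola CRM	event_crm	Rf1 canola	canola
CaMV	CaMV positive sample	virus		
ctp2/CP4-epsps	NK603 maize CRM	event_crm	NK603 maize	maize
ctp4/CP4-epsps	GTS 40-3-2 soy CRM	event_crm	GTS 40-3-2 soy	soy
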