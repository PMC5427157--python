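# Certified reference materials used for specificity verification (supplier catalogue).
# pct_gmo is the certified GMO mass fraction in percent as printed by the supplier
# (">99.99" style bounds kept verbatim). Bt63 rice has no reference material and is absent.
supplier_code	pct_gmo	event
AOCS 0707-B	>99.99	A2704-12 soy
AOCS 0707-C	>99.99	A5547-127 soy
AOCS 0911-C	96.32	CV127 soy
ERM-BF436b	98.6	DAS44406 soy
ERM-BF432d	10	DAS68416 soy
ERM-BF437b	98.6	DAS81419 soy
ERM-BF426d	10	DP305423 soy
ERM-BF425d	10	DP356043 soy
AOCS 0610-A	>99.99	FG72 soy
ERM-BF410g	10	GTS 40-3-2 soy
AOCS 0809-A	>99.94	MON87701 soy
AOCS 0210-A	>99.4	MON87705 soy
AOCS 0311-A	>99.05	MON87708 soy
AOCS 0809-B	>99.94	MON87769 soy
AOCS 0906-B	>99.40	MON89788 soy
ERM-BF420c	9.8	3272 maize
AOCS 0411-D	>99.88	5307 maize
ERM-BF412f	4.89	Bt11 maize
ERM-BF411f	5	Bt176 maize
Fluka 69407	1	CBH351 maize
ERM-BF433d	10	DAS40278 maize
ERM-BF424d	9.78	DAS59122 maize
JRC	1	DAS59132 (E32) maize
ERM-BF427d	10	DP98140 maize
ERM-BF414f	4.29	GA21 maize
AOCS 1208-A	>99.88	MIR162 maize
ERM-BF423d	9.85	MIR604 maize
ERM-BF413f	5	MON810 maize
ERM-BF416d	9.85	MON863 maize
AOCS 0512-A	>99.94	MON87427 maize
AOCS 0709-A	>99.05	MON87460 maize
AOCS 0406-D	>99.05	MON88017 maize
AOCS 0906-E	>99.425	MON89034 maize
ERM-BF415f	4.91	NK603 maize
AOCS 0306-H	>99.99	T25 maize
ERM-BF418d	9.86	TC1507 maize
ERM-BF434b	98.8	DP073496 canola
AOCS 1011-A	>99.94	MON88302 canola
AOCS 0711-A	>99.99	Ms1 canola
AOCS 0306-F	>99.99	Ms8 canola
AOCS 0711-B	>99.99	Rf1 canola
AOCS 0711-C	>99.99	Rf2 canola
AOCS 0306-G	>99.99	Rf3 canola
AOCS 0304-B	>99.19	GT73 canola
AOCS 0208-A	>99.99	T45 canola
AOCS 0711-D	>99.99	TOPAS 19/2 canola
ERM-BF421b	100	EH92-527-1 potato
ERM-BF422d	10	281-24-236x3006-210-23 cotton
ERM-BF428c	10	GHB119 cotton
AOCS 1108-A	>99.99	GHB614 cotton
AOCS 0306-E	>99.99	LL25 cotton
AOCS 0804-B	>99.4	MON1445 cotton
AOCS 0804-D	>98.45	MON15985 cotton
AOCS 0804-C	>97.39	MON531 cotton
AOCS 0906-D	>99.4	MON88913 cotton
ERM-BF429c	10	T304-40 cotton
EURL-GMFF	0.1	LL601 rice
AOCS 0306-I	>99.99	LL62 rice
ERM-BF419b	100	H7-1 sugar beet
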