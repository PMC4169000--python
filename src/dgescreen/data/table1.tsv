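# Characterised transcripts: wnt3 knockdown z-score, DGE class, in situ
# expression pattern type, cnidarian-restriction and ORF-completeness flags.
# Patterns: O oral, O_endo oral + later endoderm, IE ingressing/endodermal,
# A aboral, D delayed, D_A mixed delayed/aboral.
name	wnt3_z	dge_class	pattern	restricted	orf_complete
WegO1	-24.6	1	O	1	1
Znf845	-21.2	2	IE	0	1
DMRT-E	-19.1	2	IE	0	1
HlhIE1	-18.7	1	IE	0	1
Mos3	-18.2	2	IE	0	1
Bra2	-18	1	O	0	1
Sulf	-17.5	1	IE	0	1
FoxA	-16.2	2	IE	0	1
FoxC	-15.5	2	IE	0	1
ZnfO	-14.8	2	O	0	1
Sox15	-14.5	2	IE	0	1
WntX1A	-13.8	1	O	0	1
Akr	-13.6	1	O_endo	0	1
WegIE1	-13.3	2	IE	1	1
HlhIE2	-12.9	2	IE	0	1
Aat	-12.4	1	O_endo	0	1
WegIE2	-12	2	IE	1	1
WegO2	-11.8	1	O	1	1
Myb	-11.4	1	O	0	1
Erg	-11.2	2	IE	0	1
Bra	-10.6	1	O	0	1
FoxQ2c	-8.4	2	IE	0	1
NotumO	-8.4	1	O	0	1
WegO3	-5	1	O_endo	0	1
Gsc	-4.6	1	O	0	1
Botch1	18.1	4	D	0	1
bZip	12	4	D_A	0	1
FoxQ2a	11	3	A	0	1
Dkk	10.2	3	A	0	1
ZnfA	10	3	A	0	1
NotumA	9.3	4	A	0	1
Botch2	8.8	4	D_A	0	1
WegD1	8.2	4	D	1	1
WegAI	8.3	3	A	1	1
Asp	7.9	4	D	0	1
WegD2	7.8	4	D	1	1
Dan1	7.3	3	A	0	1
ZpdA	7.3	4	D_A	0	1
Amt	6.9	4	D	0	1
HD02	7	4	D	0	1
WegA2	6.9	3	A	1	1
Notch	6.7	3	D_A	0	1
UCP	6.8	4	D	0	1
Tbx	6.5	3	A	0	1
sFRP-A	6.2	3	A	0	1
Fz3	5.4	3	A	0	1
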