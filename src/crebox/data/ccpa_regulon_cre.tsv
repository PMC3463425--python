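gene	operon	strand	cre_sequence	fc_low	sig_low	fc_med	sig_med	fc_high	sig_high	dist_tss	group
acoR	acoR	upper	TGAAAGCGCTTTAT	-4.8	1	-18.7	1	-21.7	1	-27	high
acsA	acsA	lower	TGAAAGCGTTACCA	-2.3	1	-2.5	1	-2.7	1	44	high
acuA	acuA	upper	TGAAAACGCTTTAT	-2.2	1	-4.6	1	-7.7	1	-26	high
amyE	amyE	upper	TGTAAGCGTTAACA	-2.6	1	-10.7	1	-12.9	1	4	high
bglP	bglP	lower	TGAAAGCGTTGACA	-2.5	1	-4.7	1	-4.6	1	-36	high
cccA	cccA	lower	TGTAAGCGTATACA	-2.2	1	-1.8	1	-2.8	1	-29	high
citM	citM	upper	TGTAAGCGGATTCA	-2.6	1	-2.7	1	-2.9	1	46	high
cstA	cstA	lower	TGAATGCGGTTACA	-2.2	1	-1.9	1	-2.4	1	32	high
dctP	dctP	upper	TGAAAACGCTATCA	-7.4	1	-12.3	1	-16.6	1	-14	high
glpF	glpF	upper	TGACACCGCTTTCA	-4.3	1	-21.9	1	-35.6	1	-27	high
gmuB	gmuB	upper	TGTAAGCGTTTTAA	-3.0	1	-15.6	1	-35.8	1	6	high
iolA-1	iolA	lower	TGAAAGCGTTTAAT	-1.8	1	-1.9	1	-2.1	1	93	high
iolA-2	iolA	lower	TGAAAACGTTGTCA	-2.2	1	-2.5	1	-2.4	1	2404	high
manR	manR	upper	TGTAAACGGTTTCT	-2.0	1	-3.7	1	-8.0	1	0	high
msmX	msmX	lower	AGAAAGCGTTTACA	-2.0	1	-2.6	1	-3.1	1	-15	high
rbsR	rbsR	upper	TGTAAACGGTTACA	-6.7	1	-15.2	1	-23.1	1	6	high
rocG	rocG	lower	TTAAAGCGCTTACA	-2.6	1	-3.5	1	-3.1	1	43	high
sacP	sacP	lower	CGAAAACGCTATCA	-2.1	1	-7.9	1	-8.1	1	-19	high
sucC	sucC	upper	TGAAAGCGCAGTCT	-2.0	1	-5.8	1	-3.4	1	0	high
treP	treP	upper	TGAAAACGCTTGCA	-3.2	1	-13.0	1	-17.5	1	372	high
uxaC	uxaC	upper	TGAAAGCGTTATCA	-2.5	1	-3.7	1	-8.9	1	1237	high
xsa	xsa	lower	TAAAAGCGCTTACA	-1.9	1	-1.8	1	-2.6	1	7	high
xylA	xylA	upper	TGGAAGCGCAAACA	-2.4	1	-11.9	1	-11.1	1	144	high
xynP	xynP	upper	TGAAAGCGCTTTTA	-4.0	1	-11.0	1	-17.9	1	230	high
yisS	yisS	upper	AGAAAACGCTTTCT	-1.9	1	-3.5	1	-3.7	1	74	high
yjmD	yjmD	upper	TGAAAGCGGTTCAA	-2.2	1	-2.4	1	-8.8	1	ND	high
ykoM	ykoM	upper	TGCAAGGGCTTTCA	-2.0	1	-3.4	1	-3.5	1	150	high
yrpD	yrpD	upper	TGATAGCGTTTTCT	-1.9	1	-8.0	1	-6.8	1	127	high
ytkA	ytkA	lower	TGTAAGCGTTTGCT	-1.9	1	-6.4	1	-6.8	1	ND	high
yulD	yulD	lower	TGAAAGCGCTATCT	-2.3	1	-4.9	1	-5.3	1	ND	high
yvfK	yvfK	lower	TTAAAGCGCTTTCA	-4.0	1	-6.1	1	-10.6	1	5	high
abnA	abnA	lower	TGTAAGCGCTTTCT	-1.8	0	-1.7	0	-2.5	1	85	low
acoA	acoA	lower	TGTAAGCGTTTGCT	-1.1	0	-1.0	0	-1.8	1	462	low
citZ	citZ	lower	TGTAAGCATTTTCT	-1.5	0	-1.8	1	-2.1	1	88	low
csbX	csbX	lower	TGAAAACGGTGCCA	-1.4	0	-2.8	1	-2.1	1	-401	low
cydA	cydA	lower	TGAAATGAATCGTT	1.6	0	1.0	0	-2.7	1	-21	low
drm	drm	lower	TGAAAACGGTTTAT	-1.3	0	-3.6	1	-3.2	1	-16	low
gntR-1	gntR	upper	TGAAAGTGTTTGCA	-1.3	0	-2.8	1	-3.2	1	-41	low
gntR-2	gntR	upper	TGAAAGCGGTACCA	-1.3	0	-2.8	1	-3.2	1	148	low
hutP	hutP	upper	TGAAACCGCTTCCA	-1.3	0	-1.9	1	-2.6	1	209	low
lcfA	lcfA	lower	TGAAAACGTTATCA	-1.4	0	-2.6	1	-2.6	1	450	low
levD	levD	lower	TGAAAACGCTTAAC	-1.5	0	-1.2	0	-2.2	1	-45	low
malA	malA	upper	TGTAAACGTTATCA	-1.7	0	-2.0	1	-2.6	1	6	low
mleN	mleN	lower	TGAAAGCGTTTTAG	-1.5	0	-3.5	1	-2.4	1	21	low
msmR	msmR	upper	TGTAACCGCTTACT	-1.7	0	-4.2	1	-12.2	1	-28	low
mtlR	mtlR	upper	TGAAAGCGTTTTAT	-1.5	0	-2.7	1	-2.5	1	-16	low
odhA	odhA	lower	TGGAAGCGTTTTTA	-1.6	0	-6.6	1	-3.4	1	21	low
pbuG	pbuG	upper	TGAAAACGTTTTTT	-1.1	0	-1.5	0	-1.9	1	245	low
pta	pta	lower	TGAAAGCGCTATAA	1.3	0	-3.2	1	-2.7	1	-55	low
resA	resA	lower	TAAAAACGCTTTCT	-1.1	0	-1.9	1	-1.9	1	-72	low
sigL	sigL	lower	GGAAAACGCTTTCA	-1.1	0	-3.1	1	-3.3	1	ND	low
wprA	wprA	upper	TGTAAGCGGTATCT	-1.6	0	-5.5	1	-4.2	1	43	low
yckB	yckB	lower	TGAAAACGCGATCA	-1.4	0	-3.5	1	-2.1	1	-48	low
ycsA	ycsA	upper	AGAAAGCGCTTACG	-1.7	0	-6.0	1	-10.3	1	67	low
ydzA	ydzA	lower	TGAAAACGTGTCCA	-1.3	0	-6.4	1	-6.4	1	9	low
yesL	yesL	upper	TGAAAGCGTTTTCC	-1.3	0	-1.6	0	-2.0	1	125	low
yfiG	yfiG	upper	AGAAAGCGGTTACA	-1.6	0	-2.7	1	-4.6	1	38	low
yncC	yncC	upper	TGTAAACGGTTACA	-1.3	0	-2.4	1	-3.8	1	84	low
yojA	yojA	lower	TGAAAGCGCTTTCT	1.1	0	-1.5	0	-1.8	1	57	low
yqgW	yqgW	upper	TGAAAACGCTATCG	-1.1	0	-4.5	1	-4.2	1	-39	low
yqgY	yqgY	upper	TGAAAATGTTTACA	-1.4	0	-5.4	1	-4.1	1	-38	low
ysbA	ysbA	lower	TGTAAGCGCTTTAT	1.0	0	-3.8	1	-7.6	1	ND	low
ysfC	ysfC	upper	TGAAAGCGTTTTTT	-1.5	0	-1.5	0	-2.0	1	196	low
yugN	yugN	lower	TGAATGCGCTTTCT	-1.7	0	-2.4	1	-2.3	1	ND	low
yuxG	yuxG	lower	TGAAAACGGATACA	-1.2	0	-4.2	1	-6.1	1	0	low
yvdG	yvdG	lower	TGTAACCGCTTTCT	-1.4	0	-1.5	0	-2.1	1	-28	low
yxlH	yxlH	upper	TTGAAACGCTTTCA	-1.4	0	-2.0	1	-2.3	1	260	low
yydK	yydK	upper	TGTAAGCGGTTTAT	-1.5	0	-3.2	1	-2.4	1	-21	low
yyzE	yyzE	lower	TGAAAGCGTAACCA	-1.2	0	-3.0	1	-2.1	1	0	low
ilvB	ilvB	lower	TGAAAGCGTATACA	3.0	1	6.2	1	2.7	1	88	activating
opuE	opuE	lower	TGAAAGCGTTTTAT	2.3	1	2.5	1	2.3	1	-103	activating
ycbP	ycbP	lower	TGAAAGCGCTCGCT	2.5	1	3.3	1	2.6	1	30	activating
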