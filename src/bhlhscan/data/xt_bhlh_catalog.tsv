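family	gene	human_ortholog	mle_bootstrap	bi_posterior	protein_accession	contig_accession
ASCa	Xsash1	Hash1 (ASCL1)	89	99	XP_002944648.1	NW_003169609.1
ASCa	Xsash2	Hash2	n/m*	99	XP_002940290.1	NW_003163913.1
ASCb	Xsash3	Hash3 (ASCL3)	90	100	XP_002940370.1	NW_003163927.1
MyoD	Myf3	Myf3	96	94	NP_988972.1	NW_003166075.1
MyoD	Myf4	Myf4	94	100	NP_001016725.1	NW_003163495.1
MyoD	Myf5	Myf5	n/m	76	NP_988932.1	NW_003163331.1
MyoD	Myf6	Myf6	82	95	NP_001017160.1	NW_003163331.1
E12/E47	E2A	E2A	99	53	NP_001093743.1	NW_003163736.1
E12/E47	TCF3	TCF3	76	88	XP_002940299.1	NW_003163915.1
E12/E47	TCF4	TCF4	76	n/m*	NP_001096226.2	NW_003163423.1
Ngn	Xsath4c	Hath4c	83	78	NP_001116895.1	NW_003163503.1
NeuroD	NDF1 (neurod1)	NDF1 (NEUROD1)	n/m	n/m*	NP_001090868.1	NW_003163341.1
NeuroD	NDF2	NDF2 (NEUROD2)	65	63	NP_001072486.1	NW_003163936.1
NeuroD	Xsath2	Hath2	79	80	NP_001072273.1	NW_003163914.1
NeuroD	Xsath3	Hath3	97	99	NP_001124513.1	NW_003163487.1
Mist1	Mist1	Mist1	99	100	XP_002931994.1	NW_003163340.1
Beta3	Beta3a	Beta3a	70	53	XP_002944506.1	NW_003167409.1
Beta3	Beta3b	Beta3b	77	94	NP_001072933.1	NW_003163515.1
Oligo	Oligo1	Oligo1	97	100	XP_002938497.1	NW_003163700.1
Oligo	Oligo2	Oligo2	76	73	XP_002938491.1	NW_003163700.1
Oligo	Oligo3	Oligo3	83	90	NP_001008191.1	NW_003163713.1
Oligo	Oligo4	Oligo1 Oligo2 Oligo3	n/m	n/m	NP_001039180.1	NW_003163795.1
Net	Xsath6	Hath6	100	100	XP_002937330.1	NW_003163606.1
Mesp	Mesp1	Mesp1 Mesp2 pMesp1	n/m	n/m	NP_001039184.1	NW_003163348.1
Mesp	Mesp2	Mesp1 Mesp2 pMesp1	n/m	n/m	NP_001016653.1	NW_003163348.1
Mesp	pMespo	pMesp1	99	100	NP_001039104.1	NW_003163426.1
Twist	Twist1	Twist1	91	83	NP_989415.1	NW_003163378.1
Twist	Twist2	Twist2	98	100	NP_001096679.1	NW_003163487.1
Paraxis	Paraxis	Paraxis	62	83	NP_001016506.1	NW_003165117.1
Paraxis	Sclerax1	Sclerax	96	99	XP_002942929.1	NW_003164455.1
Paraxis	Sclerax2	Sclerax	74	59	XP_002937913.1	NW_003163647.1
MyoRa	MyoRa1	MyoRa1	63	60	NP_001096235.1	NW_003163586.1
MyoRa	MyoRa2	MyoRa2	n/m	62	NP_001103518.1	NW_003163498.1
MyoRb	MyoRb1	MyoRb1	78	94	GNOMON|93674.p	NW_003164157.1
MyoRb	MyoRb2	MyoRb2	55	95	GNOMON|522504.p	NW_003163470.1
Hand	Hand1	Hand1	94	100	NP_001016743.1	NW_003163350.1
Hand	Hand2	Hand2	99	55	NP_001093695.1	NW_003163380.1
PTFa	PTFa	PTFa	99	100	NP_001095279.1	NW_003163378.1
PTFb	PTFb	PTFb	91	100	XP_002933181.1	NW_003163373.1
SCL	Tal1	Tal1	77	62	NP_001135468.1	NW_003163327.1
SCL	Tal2	Tal2	72	76	XP_002934026.1	NW_003163404.1
SCL	Lyl1	Lyl1	86	97	XP_002939165.1	NW_003163774.1
NSCL	NSCL1	NSCL1	99	100	XP_002937307.1	NW_003163605.1
SRC	SRC1	SRC1	82	97	NP_001106383.1	NW_003163796.1
SRC	SRC2	SRC2	97	100	NP_001135631.1	NW_003163586.1
SRC	SRC3	SRC3	80	97	XP_002933204.1	NW_003163374.1
Figα	Figα	Figα	92	100	NP_001016342.1	NW_003163469.1
MYC	l-Myc	L-Myc	71	65	NP_001011144.1	NW_003164143.1
MYC	n-Myc	n-Myc	n/m	98	NP_989390.1	NW_003163721.1
MYC	v-Myc	v-Myc	91	99	NP_001006874.1	NW_003163866.1
Mad	Mxi1	Mxi1	85	97	NP_001008129	NW_003180496.1 NW_003163820.1
Mad	Mad1	Mad1	n/m	88	NP_001072228.1	NW_003163469.1
Mad	Mad3	Mad3	99	100	NP_001017299.1	NW_003163577.1
Mad	Mad4	Mad4	89	100	NP_001096239.1	NW_003164437.1
Mnt	Mnt	Mnt	n/m	97	NP_001135494.1	NW_003163468.1
MAX	MAX	MAX	90	100	NP_001008208.1	NW_003163599.1
USF	USF1	USF1	92	99	NP_001096236.1	NW_003168160.1
USF	USF2	USF2	n/m	60	NP_001007857.1	NW_003163677.1
USF	USF3	USF3	85	99	NP_001120597.1	NW_003164188.1
MITF	MITF	MITF	n/m	n/m	NP_001093747.1	NW_003163951.1
MITF	TFEb	TFEb	84	100	NP_001072648.1	NW_003163367.1
MITF	TFEc	TFEc	66	99	XP_002935013.1	NW_003163447.1
MITF	TFE3	TFE3	85	78	XP_002944430.1	NW_003166883.1
SREBP	SREBP1a	SREBP1	88	99	XP_002935886.1	NW_003163500.1
SREBP	SREBP1b	SREBP1	88	99	XP_002935887.1	NW_003163500.1
SREBP	SREBP1c	SREBP1	88	99	XP_002944649.1	NW_003169615.1 NW_003163500.1
SREBP	SREBP2	SREBP2	n/m	67	NP_001116910.1	NW_003163395.1
AP4	AP4	AP4	71	98	NP_001123841.1	NW_003163353.1
Mlx	MondoA	MondoA	89	100	NP_001090682.1	NW_003163637.1
TF4	TF4	TF4	88	100	GNOMON:712044.p	NW_003164277.1, NW_003164157.1
Clock	Clock	Clock	99	100	NP_001122127.1	NW_003163433.1
ARNT	ARNT1	ARNT1	n/m	n/m	NP_001116925.1	NW_003163477.1
ARNT	ARNT2	ARNT2	100	n/m	NP_001093686.1	NW_003163348.1
Bmal	Bmal2	Bmal2	63	100	NP_001096298.1	NW_003164805.1
AHR	AHR1	AHR1	92	99	XP_002933348.1	NW_003163378.1
AHR	AHR2	AHR2	91	100	XP_002935182.1	NW_003163457.1
Sim	Sim1	Sim1	n/m*	98	XP_002932187.1	NW_003163345.1
Sim	Sim2	Sim2	89	99	XP_002941575.1	NW_003164120.1
Trh	NPAS3	NPAS3	n/m	70	NP_001072647.1	NW_003163363.1
HIF	Hif1α	Hif1α	99	n/m	NP_001011165.1	NW_003163817.1
HIF	EPAS1	EPAS1	79	94	NP_001005647.1	NW_003163351.1
Emc	Id2	Id2	78	90	NP_988885.1	NW_003163451.1
Emc	Id3	Id3	79	98	NP_001016271.1	NW_003163432.1
Emc	Id4	Id4	86	54	NP_001004839.1	NW_003163385.1
Hey	Herp1	Herp1	83	97	NP_001007911.1	NW_003163551.1
Hey	Herp2	Herp2	86	92	XP_002936042.1	NW_003163507.1
Hey	HEYL	HEYL	98	100	XP_002934312.1	NW_003163416.1
H/E(spl)	Dec2	Dec2	99	n/m	NP_001027504.1	NW_003163993.1
H/E(spl)	Hes1a	Hes1	n/m	81	NP_001011194.1	NW_003163571.1
H/E(spl)	Hes1b	Hes1	n/m	81	NP_988870.1	NW_003163533.1
H/E(spl)	Hes5a	Hes5	n/m*	61	NP_001037880.1	NW_003163546.1
H/E(spl)	Hes5b	Hes5	n/m*	61	NP_001037974.1	NW_003163546.1
H/E(spl)	Hes5c	Hes5	n/m*	100	NP_001039178.1	NW_003163399.1
H/E(spl)	Hes5d	Hes5	n/m*	100	NP_001037951.1	NW_003163399.1
H/E(spl)	Hes5e	Hes5	n/m*	82	NP_001107462.1	No finding
H/E(spl)	Esr9	Hes5	n/m*	100	NP_001037989.1	NW_003163399.1
H/E(spl)	Hes6	Hes6	n/m	n/m	NP_001072210.1	NW_003163381.1
H/E(spl)	Hes7a	Hes7	73	97	NP_001039166.1	NW_003164377.1
H/E(spl)	Hes7b	Hes7	86	100	NP_001107508.1	NW_003164377.1
Coe	EBF1	EBF1	n/m	51	XP_002939654.1	NW_003163834.1
Coe	EBF2	EBF2	91	97	NP_989200.1	NW_003163356.1
Coe	EBF3	EBF3	91	66	XP_002932694.1	NW_003163358.1
Coe	EBF4	EBF4	91	66	XP_002932695.1	NW_003163358.1
Orphan	Orphan1	Orphan1	86	100	XP_002938975.1	NW_003163749.1
Orphan	Orphan4	Orphan4	94	100	XP_002943245.1	NW_003164609.1
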