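# Celiac-disease-active T-cell epitope table (9-mer cores, deamidated form as
# published; native form recovered by reverting transglutaminase deamidation E->Q).
# SYNTHETIC TRANSCRIPTION: the published figure is not redistributable here, so this
# table is a reconstruction from the Sollid et al. (2019) epitope nomenclature and
# the sequences quoted in the accompanying study text. It preserves the documented
# structure exactly: 38 published epitopes, 27 nonredundant native sequences,
# 23 present in Triticum proteins (PI, PYF, PYP, PYI are barley/oat-assigned).
# protein_type: glia-alpha/glia-gamma/glia-omega gliadins, glut-L (LMW-GS),
# glut-H (HMW-GS), hor hordein, sec secalin, ave avenin.
name	full_name	deamidated_seq	restriction	protein_type	in_triticum
FR	DQ2.5-glia-a3	FRPEQPYPQ	DQ2.5	glia-alpha	yes
PFY	DQ2.5-glia-a1a	PFPQPELPY	DQ2.5	glia-alpha	yes
PYY	DQ2.5-glia-a1b	PYPQPELPY	DQ2.5	glia-alpha	yes
PLQ	DQ2.5-glia-a2	PQPELPYPQ	DQ2.5	glia-alpha	yes
QGS	DQ8-glia-a1	EGSFQPSQE	DQ8	glia-alpha	yes
QGS	DQ8.5-glia-a1	EGSFQPSQE	DQ8.5	glia-alpha	yes
QGV	DQ2.2-glia-a1	EGVFQPSQE	DQ2.2	glia-alpha	yes
QYI	DQ8-glia-a2	QYIQPEQPQ	DQ8	glia-alpha	yes
IQ	DQ2.5-glia-g2	IQPEQPAQL	DQ2.5	glia-gamma	yes
PSQ	DQ2.5-glia-g1	PQQSFPEQQ	DQ2.5	glia-gamma	yes
PSQ	DQ2.2-glia-g1	PQQSFPEQQ	DQ2.2	glia-gamma	yes
PSQ	DQ8.5-glia-g1	PQQSFPEQE	DQ8.5	glia-gamma	yes
SQ	DQ2.5-glia-g4a	SQPEQEFPQ	DQ2.5	glia-gamma	yes
PQQ	DQ2.5-glia-g4b	PQPEQEFPQ	DQ2.5	glia-gamma	yes
PQC	DQ2.5-glia-g4d	PQPEQPFCQ	DQ2.5	glia-gamma	yes
QPP	DQ2.5-glia-g4c	QQPEQPFPQ	DQ2.5	glia-gamma	yes
QPP	DQ8-glia-g1b	EQPQQPFPE	DQ8	glia-gamma	yes
QPY	DQ2.5-glia-g3	QQPEQPYPQ	DQ2.5	glia-gamma	yes
QPY	DQ8-glia-g1a	EQPQQPYPE	DQ8	glia-gamma	yes
QFP	DQ2.5-glia-g5	QQPFPEQPQ	DQ2.5	glia-gamma	yes
LQ	DQ2.5-glia-g6	LQPEQPFPQ	DQ2.5	glia-gamma	yes
PFF	DQ2.5-glia-w3	PFPEQPFPF	DQ2.5	glia-omega	yes
PQW	DQ2.5-glia-w2	PQPEQPFPW	DQ2.5	glia-omega	yes
PQW	DQ2.5-hor-2	PQPEQPFPW	DQ2.5	hor	yes
PQW	DQ2.5-sec-2	PQPEQPFPW	DQ2.5	sec	yes
PFP	DQ2.5-glia-w1	PFPQPEQPF	DQ2.5	glia-omega	yes
PFP	DQ2.5-hor-1	PFPQPEQPF	DQ2.5	hor	yes
PFP	DQ2.5-sec-1	PFPQPEQPF	DQ2.5	sec	yes
FS	DQ2.5-glut-L2	FSQQQESPF	DQ2.5	glut-L	yes
PFV	DQ2.5-glut-L1	PFSEQEQPV	DQ2.5	glut-L	yes
PFV	DQ2.2-glut-L1	PFSEQEQPV	DQ2.2	glut-L	yes
QGY	DQ8-glut-H1	QGYYPTSPE	DQ8	glut-H	yes
QGY	DQ8.5-glut-H1	QGYYPTSPE	DQ8.5	glut-H	yes
PFI	DQ2.5-sec-3	PFIQPEQPF	DQ2.5	sec	yes
PI	DQ2.5-hor-3	PIPEQPQPY	DQ2.5	hor	no
PYF	DQ2.5-ave-1a	PYPEQEEPF	DQ2.5	ave	no
PYP	DQ2.5-ave-1b	PYPEQPQPF	DQ2.5	ave	no
PYI	DQ2.5-ave-2	PYIQPEQPI	DQ2.5	ave	no
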