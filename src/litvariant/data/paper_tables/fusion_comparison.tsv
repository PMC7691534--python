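# Benchmark fixture: per-fusion-pair reference counts for fusion events found
# both by a full-text literature index (mm_refs) and in the COSMIC curated
# fusion database (cosmic_refs).
fusion	mm_refs	cosmic_refs
RUNX1-RUNX1T1	2706	55
ETV6-JAK2	365	8
ETV6-RUNX1	1940	43
PML-RARA	1477	42
HEY1-NCOA2	51	2
TPM3-ROS1	22	1
SLC45A3-ELK4	37	2
FGFR3-TACC3	238	14
TMPRSS2-ERG	1895	114
ETV6-PDGFRB	252	16
NPM1-ALK	1322	86
TCF3-PBX1	796	53
EPC1-PHF1	43	3
FUS-ERG	228	16
NAB2-STAT6	168	12
EWSR1-PBX1	28	2
PAX3-NCOA2	28	2
PAX3-NCOA1	41	3
FUS-CREB3L1	66	5
ETV6-NTRK3	641	49
EWSR1-CREB1	143	11
MN1-ETV6	87	7
CLTC-TFE3	48	4
PAX3-FOXO1	835	72
ETV6-ABL1	283	25
MEAF6-PHF1	33	3
DNAJB1-PRKACA	66	6
IRF2BP2-CDX1	11	1
SS18L1-SSX1	11	1
PRCC-TFE3	119	11
FUS-FEV	32	3
NUP214-ABL1	167	16
CCDC6-RET	1652	164
SLC45A3-ERG	30	3
STRN-ALK	49	5
CIC-FOXO4	29	3
FUS-DDIT3	461	48
ASPSCR1-TFE3	314	33
JAZF1-PHF1	57	6
EWSR1-NFATC2	19	2
EWSR1-PATZ1	19	2
FUS-CREB3L2	112	12
SQSTM1-ALK	28	3
FGFR3-BAIAP2L1	27	3
PAX7-FOXO1	496	56
FUS-ATF1	42	5
SLC45A3-BRAF	25	3
EWSR1-FLI1	1387	167
NONO-TFE3	33	4
EWSR1-ATF1	384	47
EWSR1-POU5F1	49	6
RANBP2-ALK	89	11
EWSR1-ZNF384	8	1
PCM1-JAK2	135	17
EWSR1-ETV1	93	12
PAX5-JAK2	30	4
TPM4-ALK	99	14
BRD3-NUTM1	42	6
JAZF1-SUZ12	131	19
TPM3-ALK	185	27
SEC31A-ALK	33	5
SS18-SSX2	904	137
MSN-ALK	39	6
EWSR1-DDIT3	173	27
CBFA2T3-GLIS2	50	8
EWSR1-ERG	559	91
EWSR1-WT1	325	55
CRTC1-MAML2	212	36
HIP1-ALK	16	3
TFG-ALK	130	25
EML4-ALK	2566	518
SET-NUP214	74	15
CLTC-ALK	122	25
ATIC-ALK	97	20
EWSR1-ETV4	63	13
PPFIBP1-ALK	14	3
CARS-ALK	28	6
EWSR1-FEV	79	17
HAS2-PLAG1	18	4
EWSR1-SP3	9	2
KIF5B-RET	230	53
SS18-SSX4	82	19
KIF5B-ALK	133	31
ERC1-RET	38	9
COL1A1-PDGFB	217	52
HMGA2-RAD51B	20	5
TCF12-NR4A3	16	4
COL1A2-PLAG1	12	3
HMGA2-LPP	63	16
SS18-SSX1	501	136
PCM1-RET	25	7
SSBP2-JAK2	14	4
TAF15-NR4A3	37	11
EWSR1-NR4A3	71	22
SLC45A3-ETV1	9	3
TMPRSS2-ETV1	100	34
EZR-ROS1	53	19
SFPQ-TFE3	20	8
TMPRSS2-ETV4	47	19
PAX8-PPARG	183	77
TRIM24-RET	22	10
SLC34A2-ROS1	91	44
EWSR1-SMARCA5	4	2
EWSR1-NFATC1	2	1
EWSR1-YY1	2	1
FGFR1-ZNF703	2	1
HMGA2-CCNB1IP1	2	1
KMT2A-MLLT3	58	36
KMT2A-MLLT1	35	33
KMT2A-FOXO4	2	2
PPFIBP1-ROS1	1	1
KMT2A-SEPT5	1	1
HMGA2-COX6C	2	2
NUP107-LGR5	1	1
ERC1-ROS1	1	1
ETV6-ITPR2	1	1
KMT2A-AFF1	63	74
HMGA2-LHFP	2	3
KMT2A-MLLT10	15	26
KMT2A-MLLT6	5	10
KMT2A-ELL	8	17
KMT2A-TET1	2	5
KMT2A-MLLT11	2	7
KMT2A-SEPT6	3	13
KMT2A-CREBBP	1	8
PRKAR1A-RET	4	38
KMT2A-EPS15	1	14
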