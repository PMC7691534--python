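# Benchmark fixture: per-gene variant counts by clinical-interpretation
# category for a full-text literature index (mm_) versus ClinVar (cv_),
# across 27 genes associated with constitutional disease.
gene	mm_total	mm_pathogenic	mm_likely_pathogenic	mm_conflict	mm_vus	mm_likely_benign	mm_benign	cv_total	cv_pathogenic	cv_likely_pathogenic	cv_conflict	cv_vus	cv_likely_benign	cv_benign	cv_other
TP63	753	30	93	0	513	0	117	318	103	33	6	74	64	38	0
PHEX	478	239	74	0	140	3	22	406	251	66	5	36	26	20	2
BBS9	585	23	51	0	376	0	135	316	60	6	31	104	53	62	0
ALMS1	1104	338	75	0	634	1	56	1918	145	223	82	875	459	132	2
IFT172	254	9	19	0	209	0	17	134	19	4	2	24	52	33	0
ATP7B	1310	366	282	14	566	30	52	1230	245	240	97	353	190	97	8
NTRK2	302	1	6	0	73	5	217	33	5	0	1	4	18	4	1
THRB	525	30	69	0	297	0	129	232	59	10	6	82	52	23	0
EDA	470	105	126	0	221	0	18	226	101	50	6	44	11	13	1
BBS2	384	36	69	0	259	0	20	187	35	28	14	62	36	12	0
GBA	852	104	182	2	551	3	10	236	114	35	10	45	9	11	6
CEP290	766	3	349	0	375	0	39	592	113	50	54	165	127	65	14
NECTIN1	320	1	12	0	247	4	56	49	6	0	0	0	17	26	0
IKBKG	703	81	116	1	501	1	3	93	56	14	3	7	5	1	7
MKKS	283	46	42	4	161	4	26	108	25	6	3	44	15	14	1
TARDBP	303	15	88	2	187	1	10	86	18	2	4	42	10	10	0
WDPCP	974	0	36	0	887	49	2	103	4	2	7	52	23	13	2
POMC	287	48	34	0	183	2	20	46	12	1	5	19	6	3	0
CFI	349	45	70	2	189	1	42	97	10	7	1	27	22	21	9
BDNF	632	0	17	0	549	0	66	23	0	2	0	3	8	10	0
CFH	845	102	127	10	416	4	186	129	22	2	1	36	33	26	9
C3	313	25	61	4	141	2	80	140	3	6	7	37	47	35	5
LEPR	692	42	47	0	261	4	338	63	6	3	2	33	4	15	0
PCSK1	414	31	84	2	235	7	55	89	7	2	3	51	22	4	0
LRRK2	962	29	126	37	460	13	297	308	10	2	10	178	61	47	0
MC4R	919	136	408	33	304	32	6	79	33	6	4	20	8	3	2
MC3R	508	21	118	10	346	4	9	4	0	0	0	0	2	0	2
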