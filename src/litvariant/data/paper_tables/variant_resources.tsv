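# Benchmark fixture: per-variant reference counts returned by four literature
# resources (a full-text genomic index, Google Scholar, PubMed, ClinVar) for
# 108 clinically encountered variants, with true-positive reference counts
# after manual assessment. Flags: ONLY = only the first resource returned any
# true-positive reference; MORE = the first resource returned more true
# positives than every other resource; MISSING:<res> = that resource held a
# reference absent from the first resource.
gene	variant	mastermind_total	mastermind_tp	google_scholar_total	google_scholar_tp	pubmed_total	pubmed_tp	clinvar_total	clinvar_tp	flags
ABCC6	R760W	8	8	10	5	0	0	0	0	MORE
ABCC8	N188S	27	27	17	11	1	1	14	14	MORE
AGA	A101V	6	5	13	3	0	0	4	4	MORE
ALPL	R152H	15	14	16	10	0	0	12	8	MORE
AMPD1	Q45K	78	31	0	0	0	0	0	0	ONLY,MORE
ANO10	D615N	5	5	4	4	0	0	1	1	MORE
ANO5	N64fs	58	58	1	0	0	0	0	0	ONLY,MORE
AP5Z1	R138X	2	2	0	0	0	0	0	0	ONLY,MORE
APC	A1358V	2	2	3	1	0	0	6	3	MISSING:ClinVar
APC	E152fs	5	5	1	1	6	3	0	0	MORE
APC	Q1244X	2	2	0	0	0	0	0	0	ONLY,MORE
APC	R2714H	3	3	1	1	1	0	2	1	MORE
ASL	R182X	6	6	5	4	0	0	2	2	MORE
ATM	E3007X	1	1	0	0	0	0	9	0	ONLY,MORE
ATM	Q2729H	5	5	2	2	3	0	3	2	MORE
ATM	S1455R	5	5	3	3	1	0	3	3	MORE
ATP7B	L795F	15	15	18	13	0	0	10	7	MORE
BMPR1A	R254C	3	3	1	0	0	0	6	4	MISSING:ClinVar
BRCA1	E638K	2	2	4	1	0	0	0	0	MORE
BRCA1	H1283R	1	1	0	0	0	0	7	5	MISSING:ClinVar
BRCA1	H239R	8	8	12	4	0	0	4	4	MORE
BRCA1	L668F	22	22	17	12	1	0	14	12	MORE
BRCA1	P897fs	12	12	4	4	0	0	18	4	MORE
BRCA1	S1139I	4	4	2	2	1	0	5	3	MORE
BRCA1	V1665M	11	11	13	6	7	0	17	12	MISSING:ClinVar
BRCA2	Q2561R	3	3	1	1	7	0	4	1	MORE
BRCA2	R1160K	2	2	1	0	4	0	2	0	ONLY,MORE
BRCA2	R118H	6	6	16	3	4	0	5	3	MORE
BRCA2	R3007G	3	3	4	3	7	0	1	0
BRCA2	S683P	1	1	1	1	4	0	0	0
BRCA2	Y3035S	15	15	18	10	4	0	13	10	MORE
CACNA2D1	D1045A	3	3	2	2	31	1	0	0	MORE
CAPN3	W373R	4	4	3	3	3	0	4	4
CCM2	R19X	12	12	11	7	1	1	0	0	MORE
CDK4	R209C	8	8	5	3	0	0	7	6	MORE
CHRNA4	R495Q	1	1	2	1	0	0	0	0
COL4A4	G545A	22	22	21	16	0	0	12	11	MORE
COX4I2	R85W	2	2	3	2	0	0	1	1
DMD	E2910V	16	16	12	7	1	1	13	9	MORE
EXT2	A202V	2	2	5	2	0	0	0	0
FAH	R174X	8	8	12	5	1	1	5	5	MORE
FANCA	L1339fs	4	4	0	0	0	0	2	2	MORE
FANCC	R179X	4	4	0	0	0	0	0	0	ONLY,MORE
FBN1	C2659X	2	2	2	1	2	0	2	1	MORE
FCN3	L117fs	27	27	15	12	0	0	4	4	MORE
FIG4	F254fs	3	3	0	0	0	0	4	3
FREM2	P187L	1	1	1	1	0	0	0	0
FTO	V201I	3	3	2	1	0	0	0	0	MORE
GCDH	G390R	4	4	12	4	1	1	4	4
HBB	G84fs	6	6	0	0	0	0	16	3	MORE
HMBS	H256Q	1	1	2	1	0	0	0	0
HNF1B	V61G	13	13	16	8	2	0	7	6	MORE
HNRNPU	R324G	2	2	2	2	0	0	13	2
HOGA1	P190L	8	8	12	7	2	2	4	4	MORE
KCNE1	R67H	10	10	17	6	1	1	8	5	MORE
KCNH2	D501N	12	12	15	8	0	0	12	9	MORE
KCNQ1	R397W	15	15	19	6	1	1	13	12	MORE
LDB3	A698T	4	4	6	4	0	0	5	4
LDLR	D304E	5	5	3	2	4	0	13	1	MORE
LDLR	D482G	1	1	4	1	7	0	1	1
LDLR	D492H	3	2	1	0	0	0	3	0	ONLY,MORE
LDLR	D622G	1	1	1	1	7	0	2	1
LDLR	F73C	1	1	1	1	7	0	0	0
LIPT1	S292X	5	5	1	1	1	1	3	1	MORE
LRRK2	R521G	3	3	20	2	0	0	1	0	MORE
MCCC1	M325R	6	6	3	2	0	0	5	3	MORE
MLH1	K461N	3	3	2	2	0	0	0	0	MORE
MLH1	S577L	3	3	1	0	0	0	5	4	MISSING:ClinVar
MLH1	V664del	2	2	0	0	0	0	0	0	ONLY,MORE
MMACHC	Y130C	6	6	4	4	1	1	2	2	MORE
MMP21	W401X	1	1	0	0	0	0	1	1
MSH2	A636V	1	1	2	1	0	0	5	0
MSH2	Q377X	2	2	9	0	0	0	0	0	ONLY,MORE
MSH2	R171K	1	1	6	1	2	0	2	2	MISSING:ClinVar
MSH6	S564X	1	1	3	0	0	0	4	1
MSH6	T767I	4	4	9	3	1	1	3	1	MORE
MUTYH	W174X	3	3	6	1	0	0	0	0	MORE
MYBPC3	S858N	10	10	10	5	1	0	9	8	MORE
MYH7	D778E	15	15	16	10	1	0	9	8	MORE
MYH7	I530V	2	2	4	1	5	0	3	3	MISSING:ClinVar
MYO7A	R336C	1	1	0	0	0	0	0	0	ONLY,MORE
MYO7A	T165M	8	8	15	9	2	2	9	9	MISSING:Google,ClinVar
MYPN	P1112L	18	18	9	8	1	1	8	7	MORE
MYPN	Y20C	15	15	24	10	1	1	6	6	MORE
OCA2	A334T	1	1	0	0	0	0	12	0	ONLY,MORE
OCA2	N489D	21	21	24	19	1	1	6	5	MORE
PAH	F39del	58	58	8	8	0	0	20	18	MORE
PALB2	T226A	1	1	0	0	0	0	0	0	ONLY,MORE
PMS2	E473K	1	1	7	1	0	0	3	1	MORE
PMS2	E661K	1	1	0	0	1	0	3	2	MISSING:ClinVar
PMS2	L729fs	15	15	0	0	0	0	0	0	ONLY,MORE
PRODH	A455S	6	6	7	5	1	1	2	2	MORE
PTCH1	G38A	1	1	6	0	0	0	0	0	ONLY,MORE
PTEN	C296X	3	3	2	2	0	0	0	0	MORE
RAD50	R138X	4	4	6	2	0	0	3	2	MORE
SETX	G2169G	1	1	1	1	36	0	0	0
SHOX	R147H	5	5	8	5	1	1	0	0
SLURP1	W15R	19	19	22	12	4	4	5	5	MORE
SMPD1	L180fs	1	1	0	0	0	0	4	1
SOS1	P340S	2	2	4	2	1	1	3	2
SURF1	D202H	15	15	5	2	0	0	0	0	MORE
TMC1	R389X	17	17	14	11	1	1	3	3	MORE
TMPRSS3	A306T	18	18	23	15	6	6	7	7	MORE
TP53	E343Q	2	2	1	1	3	0	0	0	MORE
TSC2	A84V	5	4	5	1	0	0	1	1	MORE
TTR	E109K	6	6	9	5	0	0	0	0	MORE
TTR	E74Q	5	4	8	2	0	0	3	3	MORE
WNK4	P556T	4	4	7	4	1	1	0	0
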