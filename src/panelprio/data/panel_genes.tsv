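gene	inheritance	refseq	cytoband	exon_count	description
ABCA4	AR/AD	NM_000350	1p22.1	50	ATP-binding cassette, sub-family A (ABC1), member 4
ARL6	AR	NM_177976	3q11.2	9	ADP-ribosylation factor-like 6
BEST1	AD	NM_001139443	11q12.3	9	bestrophin 1
C2ORF71	AR	NM_001029883	2p23.2	2	chromosome 2 open reading frame 71
CA4	AD	NM_000717	17q23.1	8	carbonic anhydrase IV
CERKL	AR	NM_201548	2q31.3	13	ceramide kinase-like
CLRN1	AR	NM_001195794	3q25.1	4	clarin 1
CNGA1	AR	NM_001142564	4p12	10	cyclic nucleotide-gated channel alpha 1
CNGB1	AR	NM_001297	16q21	33	cyclic nucleotide-gated channel beta 1
CRB1	AR	NM_201253	1q31.3	12	crumbs homolog 1
CRX	AD	NM_000554	19q13.33	4	cone-rod homeobox
DHDDS	AR	NM_024887	1p36.11	9	dehydrodolichyl diphosphate synthase
EYS	AR	NM_001142800	6q12	43	eyes shut homolog
FAM161A	AR	NM_001201543	2p15	7	family with sequence similarity 161, member A
FSCN2	AD	NM_001077182	17q25.3	5	fascin homolog 2, actin-bundling protein, retinal
GUCA1B	AD	NM_002098	6p21.1	4	guanylate cyclase activator 1B
IDH3B	AR	NM_006899	20p13	12	isocitrate dehydrogenase 3 (NAD+) beta
IMPDH1	AD	NM_000883	7q32.1	17	IMP dehydrogenase 1
IMPG2	AR	NM_016247	3q12.3	19	interphotoreceptor matrix proteoglycan 2
KLHL7	AD	NM_001031710	7p15.3	11	kelch-like family member 7
LRAT	AR	NM_004744	4q32.1	3	lecithin retinol acyltransferase
MERTK	AR	NM_006343	2q13	19	c-mer proto-oncogene tyrosine kinase
NR2E3	AR/AD	NM_016346	15q23	8	nuclear receptor subfamily 2, group E, member 3
NRL	AD	NM_006177	14q11.2	3	neural retina leucine zipper
PDE6A	AR	NM_000440	5q32	22	phosphodiesterase 6A, cGMP-specific, rod, alpha
PDE6B	AR	NM_000283	4p16.3	22	phosphodiesterase 6B, cGMP-specific, rod, beta
PDE6G	AR	NM_002602	17q25.3	4	phosphodiesterase 6G, cGMP-specific, rod, gamma
PRCD	AR	NR_033357	17q25.1	5	progressive rod-cone degeneration
PROM1	AR	NM_006017	4p15.32	27	prominin 1
PRPF3	AD	NM_004698	1q21.2	16	PRP3 pre-mRNA processing factor 3 homolog
PRPF31	AD	NM_015629	19q13.42	14	PRP31 pre-mRNA processing factor 31 homolog
PRPF8	AD	NM_006445	17p13.3	43	PRP8 pre-mRNA processing factor 8 homolog
PRPH2	AD	NM_000322	6p21.1	3	peripherin 2 (retinal degeneration, slow)
ROM1	digenic	NM_000327	11q12.3	3	retinal outer segment membrane protein 1
RBP3	AR	NM_002900	10q11.2	4	retinol binding protein 3, interstitial
RDH12	AR	NM_152443	14q24.1	9	retinol dehydrogenase 12
RGR	AR/AD	NM_002921	10q23.1	7	G protein coupled receptor
RHO	AR/AD	NM_000539	3q22.1	5	rhodopsin
RLBP1	AR	NM_000326	15q26.1	9	retinaldehyde-binding protein 1
RP1	AR/AD	NM_006269	8q12.1	4	retinitis pigmentosa 1
RP2	X-linked	NM_006915	Xp11.23	5	retinitis pigmentosa 2 (X-linked recessive)
RP9	AD	NM_203288	7p14.3	6	retinitis pigmentosa 9
RPE65	AR	NM_000329	1p31.3	14	retinal pigment epithelium-specific protein 65 kDa
RPGR	X-linked	NM_001034853	Xp11.4	15	retinitis pigmentosa GTPase regulator
SAG	AR	NM_000541	2q37.1	16	S-antigen; retina and pineal gland (arrestin)
SEMA4A	AR/AD	NM_001193300	1q22	15	semaphorin 4A
SNRNP200	AD	NM_014014	2q11.2	45	small nuclear ribonucleoprotein 200 kDa (U5)
SPATA7	AR	NM_018418	14q31.3	12	spermatogenesis-associated 7
TOPORS	AD	NM_005802	9p21.1	3	topoisomerase I binding, arginine/serine-rich, E3 ubiquitin protein ligase
TTC8	AR	NM_144596	14q31.3	15	tetratricopeptide repeat domain 8
TULP1	AR	NM_003322	6p21.31	15	Tubby-like protein 1
USH2A	AR	NM_206933	1q41	72	Usher syndrome 2A
ZNF513	AR	NM_144631	2p23.3	4	zinc finger protein 513
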