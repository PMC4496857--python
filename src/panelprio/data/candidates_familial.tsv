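unit_id	inheritance	gene	genotype	chrom	exon	hgvs_c	hgvs_p	consequence	reference	af_evs	af_1kg	af_inhouse	polyphen2	sift	mutpred	printed_class
F03	AD	RP1	Hetero	8	4	c.1455T>G	p.Y485X	nonsense	novel							II
F04	X-L	RP2	Hemi	X	2	c.340T>C	p.C114R	nonsynonymous	novel				probably_damaging	damaging	0.85	II
F06	AD	RP1	Hetero	8	4	c.2296C>T	p.Q766X	nonsense	novel							II
F07	AD	PRPF31	Hetero	19	6	c.421-1G>A		splicing	Xia et al.							I
F09	AD	RHO	Hetero	3	5	c.1040C>T	p.P347L	nonsynonymous	rs29001566				probably_damaging	damaging	0.95	I
F10	AD	KLHL7	Hetero	7	5	c.458C>T	p.A153V	nonsynonymous	rs137853113				probably_damaging	damaging	0.72	I
F12	X-L	RP2	Hemi	X	2	c.560_561delGC	p.Ser187fs	frameshift_deletion	novel							II
F13	AD	RHO	Hetero	3	3	c.533A>G	p.Y178C	nonsynonymous	rs104893776				probably_damaging	damaging	0.90	I
XF1	AD	TOPORS	Hetero	9	2	c.2344C>T	p.R782X	nonsense	novel			0.0052083				II
XF3	AD	PRPF31	Hetero	19	10	c.1060C>T	p.R354X	nonsense	Sullivan et al.							I
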