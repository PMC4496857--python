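unit_id	inheritance	gene	genotype	chrom	exon	hgvs_c	hgvs_p	consequence	reference	af_evs	af_1kg	af_inhouse	polyphen2	sift	mutpred	printed_class
430	AD	PRPF31	Hetero	19	1	c.310G>A	p.E104K	nonsynonymous	novel				probably_damaging	damaging	0.78	II
432	AD	PRPH2	Hetero	6	1	c.380A>G	p.E127G	nonsynonymous	novel				possibly_damaging	damaging	0.66	II
436	AR	PDE6B	Compound hetero	4	8	c.832C>T	p.H278Y	nonsynonymous	rs121918581				probably_damaging	damaging	0.93	I
436	AR	PDE6B	Compound hetero	4	1	c.32G>A	p.W11X	nonsense	novel							II
438	AR	USH2A	Compound hetero	1	42	c.8885T>G	p.L2962R	nonsynonymous	novel				probably_damaging	damaging	0.81	II
438	AR	USH2A	Compound hetero	1	18	c.4460G>A	p.W1487X	nonsense	novel							II
439	AR	EYS	Compound hetero	6	8	c.1750G>T	p.E584X	nonsense	novel							II
439	AR	EYS	Compound hetero	6	26	c.4958_4959insA	p.S1653fs	frameshift_insertion	novel							II
440	AR	EYS	Compound hetero	6	29	c.6557G>A	p.G2186E	nonsynonymous	Littink et al.				probably_damaging	damaging	0.88	I
440	AR	EYS	Compound hetero	6	26	c.4958_4959insA	p.S1653fs	frameshift_insertion	novel							II
445	AR	PDE6B	Compound hetero	4	8	c.832C>T	p.H278Y	nonsynonymous	rs121918581				probably_damaging	damaging	0.93	I
445	AR	PDE6B	Compound hetero	4	8	c.767T>A	p.I256N	nonsynonymous	novel				probably_damaging	damaging	0.70	II
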