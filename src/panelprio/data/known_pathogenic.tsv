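gene	hgvs_c	hgvs_p	rsid	citation
PRPF31	c.421-1G>A			Xia et al.
RHO		p.P347L	rs29001566	Dryja et al.
KLHL7		p.A153V	rs137853113	Friedman et al.
RHO		p.Y178C	rs104893776	Sung et al.
PRPF31	c.1060C>T	p.R354X		Sullivan et al.
PDE6B	c.832C>T	p.H278Y	rs121918581	McLaughlin et al.
EYS		p.G2186E		Littink et al.
EYS		p.Y2935X		Iwanami et al.
USH2A		p.C3416G		McGee et al.
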