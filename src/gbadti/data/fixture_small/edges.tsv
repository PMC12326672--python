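drug_id	protein_id	label
d0000	p0000	1
d0000	p0001	1
d0000	p0002	1
d0001	p0000	1
d0001	p0001	1
d0001	p0002	1
d0002	p0000	1
d0002	p0001	1
d0002	p0002	1
d0003	p0003	1
d0003	p0004	1
d0003	p0005	1
d0004	p0003	1
d0004	p0004	1
d0004	p0005	1
d0005	p0003	1
d0005	p0004	1
d0005	p0005	1
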