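entity_id	kind	cluster
d0000	drug	0
d0001	drug	0
d0002	drug	0
d0003	drug	1
d0004	drug	1
d0005	drug	1
p0000	protein	0
p0001	protein	0
p0002	protein	0
p0003	protein	1
p0004	protein	1
p0005	protein	1
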