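[model]
id	TOY-B
collection	toy
[compounds]
M	c
N	c
N	e
[reactions]
T_B	0	100	
R_B	0	100	
BIO_B	0	100	biomass
[stoichiometry]
T_B	N	c	1
T_B	N	e	-1
R_B	M	c	1
R_B	N	c	-1
BIO_B	M	c	-1
[environment]
N	-10	0
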