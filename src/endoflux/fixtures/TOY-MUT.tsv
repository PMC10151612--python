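[model]
id	TOY-MUT
collection	toy
[compounds]
A	c
A	e
B	c
[reactions]
T_M	0	5	
R_M	0	100	
BIO_M	0	100	biomass
[stoichiometry]
T_M	A	c	1
T_M	A	e	-1
R_M	A	c	-1
R_M	B	c	1
BIO_M	B	c	-1
[environment]
A	-10	0
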