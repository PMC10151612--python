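[model]
id	TOY-A-RAW
collection	toy
[compounds]
A	c
A	e
B	c
[reactions]
T_A	0	100	
R_A	0	100	
BIO_A	0	100	biomass
EX_A	-10	0	exchange
[stoichiometry]
T_A	A	c	1
T_A	A	e	-1
R_A	A	c	-1
R_A	B	c	1
BIO_A	B	c	-1
EX_A	A	e	-1
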