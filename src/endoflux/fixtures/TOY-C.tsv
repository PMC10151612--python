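[model]
id	TOY-C
collection	toy
[compounds]
A	c
A	e
D	e
P	c
[reactions]
RD_C	0	100	
TA_C	-100	100	
BIO_C	0	100	biomass
[stoichiometry]
RD_C	D	e	-1
RD_C	P	c	1
TA_C	A	c	1
TA_C	A	e	-1
BIO_C	P	c	-1
[environment]
D	-10	0
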