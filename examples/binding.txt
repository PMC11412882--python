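*Time
0	10000	1000	1000	10	Steps
*Element
A	10000	tab:blue
B	10000	tab:orange
C	0	tab:green
*Reaction	10000.0
standard	bind	1	A	1	B	1.0	1	C
*Plot	line
A	B	C
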