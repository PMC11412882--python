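*Time
0	10000	1000	1000	10	Steps
*Element
S	10000	tab:blue
E	1000	tab:orange
ES	0	tab:green
P	0	tab:red
*Reaction	10000.0
standard	binding	1	S	1	E	1.0	1	ES
mono	unbinding	1	ES	0.1	1	S	1	E
mono	catalysis	1	ES	0.1	1	E	1	P
*Plot	line
E	ES
*Plot	line
S	P
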