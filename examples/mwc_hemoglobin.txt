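*Time
0	10000	1000	1000	10	Steps
*Element
O2	10000	tab:cyan
Hb	1000	tab:blue
Hb(O2)	0	tab:orange
Hb(O2)2	0	tab:green
Hb(O2)3	0	tab:red
Hb(O2)4	0	tab:purple
*Reaction	10000.0
standard	bind_o2_1	1	Hb	1	O2	0.1	1	Hb(O2)
standard	bind_o2_2	1	Hb(O2)	1	O2	0.5	1	Hb(O2)2
standard	bind_o2_3	1	Hb(O2)2	1	O2	10.0	1	Hb(O2)3
standard	bind_o2_4	1	Hb(O2)3	1	O2	50.0	1	Hb(O2)4
*Plot	line
Hb	Hb(O2)	Hb(O2)2	Hb(O2)3	Hb(O2)4
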