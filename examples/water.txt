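*Time
0	20000	1000	1000	10	Steps
*Element
H2O	20000000000000000000	tab:blue
H+	0	tab:red
OH-	0	tab:green
*Reaction	2e19
mono	dissociation	1	H2O	1.010100909090919e-09	1	H+	1	OH-
standard	recombination	1	H+	1	OH-	100000.0	1	H2O
*Plot	line
H+	OH-
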