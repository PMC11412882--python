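*Time
0	50000	1000	1000	100	Steps
*Element
Sx	0	tab:blue
Sy	0	tab:orange
pX	500
pX*	0	tab:green
pY	0
pY*	0	tab:red
pZ	0	tab:purple
DNA-Y	1
DNA-Y_X*	0	tab:brown
DNA-Z	1
DNA-Z_X*_Y*	0	tab:pink
*Reaction	1000.0
standard	x_activation	1	Sx	1	pX	10.0	1	pX*
standard	y_activation	1	Sy	1	pY	10.0	1	pY*
standard	y_gene_binding	1	pX*	1	DNA-Y	10.0	1	DNA-Y_X*
mono	y_expression	1	DNA-Y_X*	1.0	1	DNA-Y_X*	1	pY
standard	z_gene_binding	1	pX*	1	pY*	1	DNA-Z	10.0	1	DNA-Z_X*_Y*
mono	z_expression	1	DNA-Z_X*_Y*	1.0	1	DNA-Z_X*_Y*	1	pZ
*ElementInOut
10000	Sx	500
20000	Sy	500
*Plot	line
Sx	Sy
*Plot	line
pX*	pY*	pZ
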