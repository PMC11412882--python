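*Time
0	5000	1000	1000	10	Steps
*Element
Stimulus	50	tab:gray
DNA_i	1
DNA	0	tab:blue
DNA_d	0	tab:red
Ribonucleotide	10000
mRNA	0	tab:green
Ribosome	10
Amino	10000
Protein	0	tab:purple
*Reaction	10000.0
standard	activation	1	Stimulus	1	DNA_i	100.0	1	DNA
standard	transcription	1	DNA	1	Ribonucleotide	1.0	1	DNA	1	mRNA
standard	translation	1	mRNA	1	Ribosome	1	Amino	10.0	1	mRNA	1	Ribosome	1	Protein
standard	deactivation	1	Protein	1	DNA	1.0	1	DNA_d
*Plot	line
DNA	DNA_d
*Plot	line
mRNA	Protein
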