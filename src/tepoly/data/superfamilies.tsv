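token	te_class	order
CR1	I	LINE
L1	I	LINE
L2	I	LINE
RTE	I	LINE
R2	I	LINE
Jockey	I	LINE
Rex1	I	LINE
SINE	I	SINE
Gypsy	I	LTR
Copia	I	LTR
Bel-Pao	I	LTR
ERV	I	LTR
DIRS	I	DIRS
Penelope	I	PLE
hAT	II	TIR
Tc1-Mariner	II	TIR
PIF-Harbinger	II	TIR
CACTA	II	TIR
PiggyBac	II	TIR
Mutator	II	TIR
Merlin	II	TIR
MITE	II	TIR
Helitron	II	Helitron
Maverick	II	Maverick
Unknown	U	Unknown
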