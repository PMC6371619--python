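node	allele	variant_string	posterior	status	genbank
Reference	Allele1	ATTGGCACCAGGCCGCCGCCCTGCTTAAGCCCTGGCGTGGTACTCGTCACGGTCCGCCGGGGCCGGATTAAA	1	Observed	KX265235
A	SPA18	------G--------------G--------T-------------T---------------------------	0.235	Predicted	na
B	SPA03	------G--------------G--------T-----------------------------------------	0.792	Predicted	na
C	SPA06	------G----------A---G--------T-----------T-T---------------------------	0.444	Predicted	na
B'	SPA03	------G--------------G--------T-----------------------------------------	0.516	Predicted	na
D	SPA09	------G----------A---G--------T---A-A-----T-T---------------------------	0.608	Predicted	na
E	SPA04	------G--------------G--------------------------------------------------	0.747	Predicted	na
F	SPA07	------G-------------TG--G--G--T-----------------------------------------	0.626	Predicted	na
G	SPA10	-C----G----------A---G--------T---A-A-----T-T---------------------------	0.594	Predicted	na
H	SPA13	-C----G----------A---G----T---T---A-A-----T-TC--------------------------	0.492	Predicted	na
I	Allele12	---------------------G--------------------------------------------------	0.621	Observed	KX265198
J	Allele18	G-----G---A--------TTG--G--G--T-----------------------------------------	0.674	Observed	KX265204
K	Allele08	------G--------------G-------------T------------------------------------	0.888	Observed	KX265194
L	Allele17	-C----G----------A---G----T---T---A-A---C-T-TC--------------------------	0.634	Observed	KX265203
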