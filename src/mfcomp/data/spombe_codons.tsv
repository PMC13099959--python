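amino_acid	codon
A	GCT
C	TGT
D	GAT
E	GAA
F	TTT
G	GGT
H	CAT
I	ATT
K	AAA
L	TTG
M	ATG
N	AAT
P	CCT
Q	CAA
R	CGT
S	TCT
T	ACT
V	GTT
W	TGG
Y	TAT
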