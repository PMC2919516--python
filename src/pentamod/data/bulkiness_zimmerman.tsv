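# Residue bulkiness scale (ratio of side-chain volume to length), as exposed
# by the ExPASy ProtScale "Bulkiness" entry.
# Source: Zimmerman JM, Eliezer N, Simha R (1968) "The characterization of
# amino acid sequences in proteins by statistical methods."
# J Theor Biol 21:170-201. Dimensionless.
# residue	value
A	11.50
R	14.28
N	12.82
D	11.68
C	13.46
Q	14.45
E	13.57
G	3.40
H	13.69
I	21.40
L	21.40
K	15.71
M	16.25
F	19.80
P	17.43
S	9.47
T	15.77
W	21.67
Y	18.03
V	21.57
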