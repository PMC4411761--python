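# Zimmerman bulkiness scale
ALA	11.50
ARG	14.28
ASN	12.82
ASP	11.68
CYS	13.46
GLN	14.45
GLU	13.57
GLY	3.40
HIS	13.69
ILE	21.40
LEU	21.40
LYS	15.71
MET	16.25
PHE	19.80
PRO	17.43
SER	9.47
THR	15.77
TRP	21.67
TYR	18.03
VAL	21.57
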