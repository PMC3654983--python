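# Amino-acid odds ratios derived from the Sup35 random-mutagenesis prion
# library (Toombs et al. "Library 1"), shipped for side-by-side comparison
# with the prion-domain table.  Not used by the scanner.
residue	odds	lor_printed
A	0.670	-0.578
C	1.520	0.604
D	0.280	-1.837
E	0.550	-0.862
F	2.310	1.208
G	0.960	-0.059
H	0.760	-0.396
I	2.260	1.176
K	0.210	-2.252
L	0.960	-0.059
M	1.960	0.971
N	1.080	0.111
P	0.300	-1.737
Q	1.070	0.098
R	0.670	-0.578
S	1.140	0.189
T	0.890	-0.168
V	2.260	1.176
W	1.950	0.963
Y	2.180	1.124
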