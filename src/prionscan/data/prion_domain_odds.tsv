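# Published amino-acid odds ratios for experimentally validated Q/N-rich
# prion-forming domains (observed frequency over Swiss-Prot background), with
# the published log2-odds in bits kept as a reference column.  The canonical
# potential used by this package is log2(odds); a few published LOr values
# differ from that by 0.001-0.009 bits because the odds were rounded to three
# decimals after the potentials were computed.
residue	odds	lor_printed
A	0.675	-0.568
C	0.071	-3.807
D	0.352	-1.507
E	0.147	-2.766
F	0.718	-0.478
G	1.028	0.040
H	0.913	-0.131
I	0.350	-1.515
K	0.271	-1.883
L	0.340	-1.556
M	1.125	0.170
N	5.700	2.511
P	1.170	0.227
Q	4.125	2.044
R	0.436	-1.196
S	1.662	0.733
T	0.830	-0.268
V	0.304	-1.716
W	0.091	-3.459
Y	1.724	0.786
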