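# Approximate ATP-equivalent amino-acid synthesis costs (precursor-excluded),
# literature-scale values for illustrative compositions only. Headline cost
# totals in this package use the published per-molecule aggregates instead.
aa	atp_equivalents
A	1.0
R	7.0
N	4.0
D	1.0
C	11.0
Q	1.0
E	1.0
G	1.0
H	7.0
I	11.0
L	1.0
K	9.0
M	18.0
F	5.0
P	4.0
S	1.0
T	6.0
W	12.0
Y	2.0
V	4.0
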