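codon	species
GCT	Ala1B
GCA	Ala1B
GCG	Ala1B
GCC	Ala2
CGT	Arg2
CGC	Arg2
CGA	Arg2
CGG	Arg3
AGA	Arg4
AGG	Arg5
AAT	Asn
AAC	Asn
GAT	Asp1
GAC	Asp1
TGT	Cys
TGC	Cys
CAA	Gln1
CAG	Gln2
GAA	Glu2
GAG	Glu2
GGT	Gly3
GGC	Gly3
GGA	Gly3
GGG	Gly3
CAT	His
CAC	His
ATT	Ile
ATC	Ile
ATA	Ile
CTG	Leu1
CTC	Leu2
CTT	Leu2
CTA	Leu3
TTG	Leu4
TTA	Leu5
AAA	Lys
AAG	Lys
ATG	Met1
TTT	Phe
TTC	Phe
CCT	Pro1
CCC	Pro1
CCA	Pro3
CCG	Pro3
TCA	Ser1
TCT	Ser1
TCG	Ser2
AGT	Ser3
AGC	Ser3
TCC	Ser5
ACT	Thr1
ACG	Thr2
ACC	Thr3
ACA	Thr4
TGG	Trp
TAT	Tyr1
TAC	Tyr1
GTT	Val1
GTC	Val1
GTA	Val1
GTG	Val1
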