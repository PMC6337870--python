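species	count
Ala1B	675.2
Ala2	122.9
Arg2	916.1
Arg3	87.1
Arg4	125.6
Arg5	94.8
Asn	235.1
Asp1	464.0
Cys	271.3
Gln1	122.2
Gln2	195.4
Glu2	929.6
Gly3	764.6
His	129.1
Ile	729.2
Leu1	821.7
Leu2	181.9
Leu3	122.9
Leu4	372.3
Leu5	140.7
Lys	336.5
Met1	58.0
Phe	180.8
Pro1	106.0
Pro3	98.3
Ser1	269.0
Ser2	52.8
Ser3	208.1
Ser5	141.8
Thr1	21.6
Thr2	102.9
Thr3	187.3
Thr4	192.3
Trp	159.9
Tyr1	2378.9
Val1	731.9
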