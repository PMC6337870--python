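species	count	source
ribosomes	1044	Rudorf & Lipowsky 2015 (actively translating, 0.064 um^3, mu = 1.1/h)
eftu	9122	Rudorf & Lipowsky 2015 (0.064 um^3, mu = 1.1/h)
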