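name	value	unit
D_m2_per_s	2.567e-12	m^2/s
k_diss_per_s	1.0	1/s
max_rate_aa_per_s	24.0	aa/ribosome/s
burn_in_steps	1000	steps
stop_steps	5000	steps
volume_um3	0.064	um^3
grid_spacing_nm	10.0	nm
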