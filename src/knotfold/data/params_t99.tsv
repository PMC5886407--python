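# pseudoknot and multiloop scalars, kcal/mol (37 C, 1 M NaCl)
P_s	9.6
P_sm	15.0
P_sp	15.0
P_b	0.2
P_up	0.1
P_ps	0.1
stP_coeff	0.83
intP_coeff	0.83
a	3.4
b	0.4
c	0.0
a2	3.4
b2	0.4
c2	0.0
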