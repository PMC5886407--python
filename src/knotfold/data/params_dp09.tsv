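# pseudoknot and multiloop scalars, kcal/mol (37 C, 1 M NaCl)
P_s	-1.38
P_sm	10.07
P_sp	15.0
P_b	2.46
P_up	0.06
P_ps	0.96
stP_coeff	0.89
intP_coeff	0.74
a	3.39
b	0.03
c	0.02
a2	3.41
b2	0.56
c2	0.12
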