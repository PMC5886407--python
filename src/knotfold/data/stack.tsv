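# stacked-pair free energies, kcal/mol: outer_pair inner_pair energy
# wobble-containing stacks carry a single flat value (see docs/methods.md)
AU	AU	-0.93
AU	UA	-1.10
AU	CG	-2.24
AU	GC	-2.08
AU	GU	-1.00
AU	UG	-1.00
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.35
UA	GC	-2.11
UA	GU	-1.00
UA	UG	-1.00
CG	AU	-2.11
CG	UA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GU	-1.00
CG	UG	-1.00
GC	AU	-2.35
GC	UA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GU	-1.00
GC	UG	-1.00
GU	AU	-1.00
GU	UA	-1.00
GU	CG	-1.00
GU	GC	-1.00
GU	GU	-1.00
GU	UG	-1.00
UG	AU	-1.00
UG	UA	-1.00
UG	CG	-1.00
UG	GC	-1.00
UG	GU	-1.00
UG	UG	-1.00
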