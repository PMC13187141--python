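# Example ligand-contact epitope spec for a BMPR2-like LBD.
# Illustrative positions only (editable fixture, NOT authoritative):
# real contact sets must be supplied by the user from their own
# structural analysis.
group	ref_pos_1based	contact_type
F1	34	polar
F1	36	hydrophobic
F1	38	polar
A-loop	60	polar
A-loop	61	hydrophobic
A-loop	63	polar
A-loop	65	polar
A-loop	66	hydrophobic
F3-loop	84	hydrophobic
F3-loop	86	polar
F3-loop	88	polar
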