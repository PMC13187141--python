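# Example ligand-contact epitope spec for a TGFBR2-like LBD.
# Illustrative positions only (editable fixture, NOT authoritative):
# real contact sets must be supplied by the user from their own
# structural analysis.
group	ref_pos_1based	contact_type
F1	28	polar
F1	30	polar
F1	32	hydrophobic
F1	35	polar
F3	76	hydrophobic
F3	78	polar
F3	80	polar
C-terminus	95	polar
C-terminus	97	hydrophobic
C-terminus	99	polar
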