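# Steroidal sapogenin backbone library (editable: add rows to extend the search space).
# Columns: name, formula, nominal protonated m/z, E/F-ring retro-cleavage loss applied to
# the sapogenin core ion (EF144 = C8H16O2; EF142 = C8H14O2 for the 27-hydroxy series, whose
# 160 Da elimination equals EF142 + H2O in mass), max sequential water losses.
name	formula	nominal_mh	ef_loss	max_water_losses
diosgenin	C27H42O3	415	EF144	4
laxogenin	C27H42O4	431	EF144	4
sarsa/tigogenin	C27H44O3	417	EF144	4
27OH-sarsa/tigogenin	C27H44O4	433	EF142	4
sieboldigenin	C27H42O5	447	EF142	4
3,6,27-triOH-furostane	C27H44O5	449	EF144	4
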