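# centroid-phase score weights: term weight
steric_rep 1.0
steric_atr 0.2
rama 0.6
omega 0.5
hbond 0.0
rotamer_pref 0.0
chainbreak 2.0
constraint 1.0
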