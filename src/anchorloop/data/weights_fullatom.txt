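# fullatom-phase score weights: term weight
steric_rep 0.55
steric_atr 0.8
rama 0.45
omega 0.5
hbond 1.2
rotamer_pref 0.56
chainbreak 2.0
constraint 1.0
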