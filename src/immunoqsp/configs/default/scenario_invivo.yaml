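# Default in-vivo study: MC38-style syngeneic mouse, treatment from a
# 100 mm^3 tumor over 25 days.  Omitted fields resolve to shipped defaults
# (registry, checkpoint profiles, solver settings).
mode: invivo
horizon: 25.0
v0_mm3: 100.0
n_out: 126
treatments: []
seed: 0
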