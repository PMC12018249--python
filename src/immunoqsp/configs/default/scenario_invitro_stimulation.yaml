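# Antibody-stimulation assay: T cells alone; add anti-CD3/anti-CD28 as
# agonist treatments with a bath concentration to drive the cascade.
mode: invitro_stimulation
horizon: 0.5
n_out: 300
densities: {T: 370.0, tumor: 0.0, APC: 0.0}
treatments: []
seed: 0
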