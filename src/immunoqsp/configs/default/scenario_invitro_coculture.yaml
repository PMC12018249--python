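# T-tumor(-APC) co-culture cytotoxicity assay at tumor-mimetic effective
# contact densities; 72 h readout of % killing and cytokine fold-change.
mode: invitro_coculture
horizon: 3.0
n_out: 100
densities: {T: 370.0, tumor: 1.0e5, APC: 10.0}
treatments: []
seed: 0
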