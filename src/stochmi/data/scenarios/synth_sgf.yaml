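# Synthetic two-reporter cytometry experiment, slow-global-fluctuation variant.
kind: synth
name: synth_sgf
variant: SGF
n_cells: 3000
seed: 7
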