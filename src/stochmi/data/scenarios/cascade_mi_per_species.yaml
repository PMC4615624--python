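# Single-cell (S1) MI from the step input to each cascade node over time.
kind: mi
name: cascade_mi_per_species
model: {name: simple_cascade, table: table1}
protocol: {type: geometric, xmax: 250.0, n: 12}
initial: S1
observables: [Y1, My2, Y2]
times: [0, 30, 75, 150, 300, 500, 750]
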