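# Homogeneous (S1) versus heterogeneous-population MI for the intrinsic cascade.
kind: mi
name: cascade_hom_vs_het
model: {name: simple_cascade, table: table1}
protocol: {type: geometric, xmax: 250.0, n: 12}
initial: heterogeneous
observables: [Y2]
times: [0, 75, 300, 750, 1500, 2750]
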