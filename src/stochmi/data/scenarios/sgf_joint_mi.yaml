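# Joint reporter+output MI for the SGF circuit, with mean-equalized reporter.
kind: mi
name: sgf_joint_mi
model: {name: circuit_global, table: table2, gamma_g: 3.0e-6, gbar: 42.0}
protocol: {type: estradiol_12}
initial: heterogeneous
observables: [Y1r, Y2]
background: default
equalize: true
times: [0, 65, 165, 330, 580]
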