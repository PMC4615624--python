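# Number of step experiments needed for a converged MI estimate (cascade).
kind: choose_n
name: cascade_choose_n
model: {name: simple_cascade, table: table1}
initial: S1
xmax: 250.0
t_min: 750.0
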