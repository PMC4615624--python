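# SSA-versus-moment cross-check for the SGF circuit at a low estradiol dose.
kind: ssa_compare
name: circuit_ssa_check
model: {name: circuit_global, table: table2, gamma_g: 3.0e-6, gbar: 42.0}
initial: S1
dose: 8.78
time: 580.0
n_runs: 1000
seed: 5
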