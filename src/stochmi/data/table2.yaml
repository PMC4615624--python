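# Synthetic-circuit parameter set, global (slow-global-fluctuation) model.
parameters:
  beta_m1: 0.667
  gamma_m1: 0.00067
  beta_y1s: 0.0000139
  gamma_y1s: 0.0000463
  theta_x: 0.002
  theta_y1: 1.5
  n1: 1.5
  y1_0: 85
  beta_m2s: 0.0
  beta_m2: 0.083
  gamma_m2: 0.00083
  beta_y2: 0.0014
  gamma_y2: 0.0000463
  gamma_y1r: 0.0000463
  alpha_x: 0.35
  x_e: 45
  n_x: 2
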