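# Simple cascade parameter set (rates in s^-1, copy numbers in molecules per cell).
parameters:
  beta_y1s: 0.01
  gamma_y1s: 0.0000067
  theta_x: 0.001
  theta_y1: 1.5
  n1: 3
  y1_0: 85
  beta_m2s: 0.0083
  beta_m2: 0.1583
  gamma_m2: 0.00083
  beta_y2: 0.0014
  gamma_y2: 0.00014
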