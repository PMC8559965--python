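parameters:
  K: 0.0025
  alpha: 2.0
  beta: 3.12e-17
  csc_window:
  - 480.0
  - 600.0
  delta: 1.44e+18
  f_T: 1.0
  f_c: 1.0
  gamma: 8.0
  k1: 1.0
  k2: 0.05
  k3: 6.56e-17
  k4: 1.0
  k5: 0.125
  k6: 1.0
  k7: 1.0
  lambda_1: 5.0e-14
  lambda_2: 915000000.0
  lambda_3: 0.0138
  lambda_B: 0.00085
  lambda_F: 0.035
  lambda_L: 1.34e-11
  lambda_X: 0.00033
  mu_A: 0.0495
  mu_B: 0.0347
  mu_C: 0.003
  mu_F: 0.3
  mu_L: 0.0815
  mu_T: 0.005
  mu_X: 0.02
  omega_1: 0.5
  omega_2: 0.5
  r: 0.07
  th_B: 8.0
  th_X: 8.0
  unit_system: dimensional
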