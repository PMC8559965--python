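horizon_days: 40.0
initial_state:
  B: 5.0
  C: 0.01
  F: 0.0
  L: 0.0
  S: 0.25
  X: 0.0
parameters:
  K: 1.0
  alpha: 2.0
  beta: 0.00560897
  csc_window:
  - 480.0
  - 600.0
  delta: 10.0
  f_T: 1.0
  f_c: 1.0
  gamma: 0.015
  k1: 1.0
  k2: 1.11034483
  k3: 4.03956522
  k4: 1.0
  k5: 0.10244565
  k6: 1.0
  k7: 0.3136
  lambda_1: 0.0001
  lambda_2: 0.05
  lambda_3: 0.025
  lambda_B: 0.16028116
  lambda_F: 0.035
  lambda_L: 0.85043478
  lambda_X: 0.006
  mu_A: 0.0495
  mu_B: 0.0347
  mu_C: 0.05
  mu_F: 0.3
  mu_L: 0.0815
  mu_T: 0.005
  mu_X: 0.02
  omega_1: 0.5
  omega_2: 0.5
  r: 0.007
  th_B: 8.0
  th_X: 8.0
  unit_system: nondimensional
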