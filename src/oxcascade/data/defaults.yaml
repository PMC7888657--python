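# Shipped calibrated parameter set: multi-start least squares on the
# built-in mutant/WT ratio table with soft barriers (fnrN fold bound;
# persistence of the hfixL-knockout low branch through the bacteroid
# O2 range), subject to the qualitative structure constraints
# (WT monostable; knockout bistable below 120 nM; descending knockout
# still on its low branch at 30 nM; WT fnrN interior maximum with
# auto-repression decline; WT fixNOQP monotone). See docs/methods.md.
# noise_sigma is the Langevin amplitude for ensemble simulations,
# chosen so the knockout commitment curve spans ~5-95% over its window.
noise_sigma: 0.2
parameters:
  A_K_dist: 3.5937277382341395
  A_K_fix: 5.145272056641193
  A_N_dist: 2.6381477208575603
  A_N_fix: 0.13619629893632093
  K_L: 1.7878035715864437e-05
  K_NO2: 2.399999999999997e-07
  K_RK: 0.5464155329986317
  alpha_F: 0.002390535788233053
  alpha_K: 0.47795791625911543
  alpha_N: 0.0001000000000000001
  beta_F: 2.286608123418731
  beta_K: 1.055979456034991
  beta_L: 1.0
  beta_N: 9.999822557647926
  beta_R: 1.0
  delta: 1.0
  henry_constant: 0.0012
  n_DNA: 2.0
  n_L: 2.0
  n_NO2: 1.0
  rho_K: 6309.155608975343
  rho_N: 1.1220184543019636
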