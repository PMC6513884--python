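astrocyte:
  alpha_eaat: 0.0032
  background_k_in_psc: true
  beta_eaat: 28.8
  ca_gecs: 0.0015
  ca_psc_0: 1.0e-07
  ca_psecs: 0.0015
  ca_soma: 1.0e-07
  g_ecs_leak: 3.3
  g_k_bg: 17.9364
  g_kir: 144.0
  g_na_bg: 0.9761
  gamma_ncx: 0.5
  glu_ecs: 2.5e-08
  glu_psc: 0.0015
  h_psc: 6.0e-08
  h_psecs: 4.0e-08
  i_bar_ncx: 1.0
  j0_eaat: 0.06
  k_gecs: 0.004
  k_ke: 0.0015
  k_nai: 0.01
  k_pf_ca: 0.0018
  k_pf_k: 0.018
  k_pf_na: 0.018
  k_psc_0: 0.1
  k_psecs_0: 0.004
  k_soma: 0.1
  kir_sqrt_k_out: false
  na_gecs: 0.135
  na_psc_0: 0.015
  na_psecs_0: 0.135
  na_soma: 0.015
  nernst_valence: false
  p_nka_max: 1.0e-06
  pf_charge_valence: false
  phi_w: 0.267
  r_g: 5.0e-07
  s_g: 9.0e-06
  tau_eaat: 0.05
  v_a: -0.0807
constants:
  F: 96485.0
  Q: 1.6022e-19
  R: 8.31
  T: 310.0
  eps0: 8.85e-12
  eps_r: 0.82
  k_B: 1.38e-23
geometry:
  l_p: 2.5e-05
  l_ps: 3.0e-07
  l_syn: 3.0e-07
  r_eps: 2.5e-07
  r_ips: 1.5e-07
  r_p: 5.0e-08
  r_syn: 1.35e-07
neuron:
  c_m: 0.01
  e_k_neu: -0.12
  e_leak_neu: 0.010613
  e_na_neu: 0.115
  g_k_bg_neu: 1.0522
  g_k_neu: 360.0
  g_leak_neu: 3.0
  g_na_bg_neu: 2.3217
  g_na_neu: 1200.0
  k_ke_neu: 0.0015
  k_nai_neu: 0.01
  k_syn: 0.1
  na_channel_h_gate: true
  na_syn: 0.015
  p_nka_max_neu: 3.7863e-08
  spike_refractory: 0.002
  spike_threshold_offset: 0.05
protocol:
  amplitude: null
  concentration_floor: 1.0e-12
  dt: 1.0e-05
  events: []
  mode: pulse
  pulse_width: 0.001
  rate: 10.0
  record_stride: 100
  seed: 0
  t_post: 60.0
  t_settle: 6.0
  t_stim: 60.0
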