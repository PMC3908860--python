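g_na: 105.0
g_k2: 30.0
g_h: 4.0
g_leak: 8.0
e_na: 0.045
e_k: -0.07
e_h: -0.021
e_leak: -0.046
c: 2.0
i_pol: -0.00600400354335309
theta_k2: -0.0075
theta_h: 0.038
k_mna: 150.0
theta_mna: 0.0305
k_hna: 500.0
theta_hna: 0.0325
tau_hna: 0.16330279762105945
k_mk2: 83.0
tau_mk2: 2.0
k_mh: 180.7425229692763
k_mh2: 500.0
tau_mh:
  t_min: 0.07
  t_amp: 0.17
  k: 100.0
  theta: 0.073
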