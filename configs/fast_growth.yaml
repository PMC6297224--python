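# Fast-growth (37 C-matched) reference condition: the calibrated defaults.
k_rp: 3.0
k_rd: 0.3
k_gp: 16.0
k_gd: 1.0
g_max: 1.6
f: 0.35
h_g: 3.0
h_r: 2.0
n_g: 2.0
n_r: -4.0
dt: 0.1
dL: 1.0
l0: 1.0
r0: 10
g0: 16
t_total: 500.0
t_burnin: 250.0
feedback_on: true
efficacy_mode: constant
seed: 0
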