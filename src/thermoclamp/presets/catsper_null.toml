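name = "catsper_null"
thermal_mode = "anchored"
notes = "Channel-null control: no gated conductance, only the temperature-insensitive residual leak (-6.1 pA/pF at -80 mV). Gating fields are placeholders and never contribute current."

v_half_cold = 0.0
v_half_hot = 0.0
k_cold = 25.0
k_hot = 25.0
q10_slow = 1.0
q10_steep = 1.0
t_threshold = 33.5
transition_center = 33.5
transition_width = 2.0
t_ref = 22.0
t_hot = 38.0

tau_ms = "none"
h_inf = 1.0

v_rev_mv = 0.0
density_anchors = [
]

leak_density_pa_pf = -6.1
cm_mean_pf = 2.45
cm_sd_pf = 0.1
cell_scale_cv = 0.2
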