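name = "capacitated_cs"
thermal_mode = "anchored"
notes = "Capacitated sperm, monovalent currents: larger membrane capacitance (2.77 pF), midpoint shift +2.5 to -47 mV, mild heat response. The 38 C density anchor is phenomenological (mild increase; not printed)."

v_half_cold = 2.5
v_half_hot = -47.0
k_cold = 42.6
k_hot = 42.6
q10_slow = 1.8
q10_steep = 2.5
t_threshold = 33.5
transition_center = 33.5
transition_width = 2.0
t_ref = 22.0
t_hot = 38.0

tau_ms = "none"
h_inf = 1.0

v_rev_mv = 0.0
density_anchors = [
    ["ramp", -80.0, 24.0, -98.2],
    ["ramp", -80.0, 38.0, -160.0],
    ["ramp", 80.0, 24.0, 150.0],
    ["ramp", 80.0, 38.0, 220.0],
    ["step", -80.0, 24.0, -98.2],
]

leak_density_pa_pf = -6.1
cm_mean_pf = 2.77
cm_sd_pf = 0.11
cell_scale_cv = 0.2
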