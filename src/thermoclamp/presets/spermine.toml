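name = "spermine"
thermal_mode = "anchored"
notes = "3 mM extracellular spermine: inward inhibition, stronger outward rectification, steeper slope factor at heat (19.2 vs 42.6) and a blunted midpoint shift (-3.7 to -25.3 mV). Density anchors are phenomenological (not printed); G-V analysis is amplitude-invariant."

v_half_cold = -3.7
v_half_hot = -25.3
k_cold = 42.6
k_hot = 19.2
q10_slow = 2.7
q10_steep = 5.01
t_threshold = 33.5
transition_center = 33.5
transition_width = 2.0
t_ref = 22.0
t_hot = 38.0

tau_ms = 25.0
h_inf = 0.3

v_rev_mv = 0.0
density_anchors = [
    ["step", -80.0, 24.0, -50.0],
    ["step", -80.0, 38.0, -70.0],
    ["step", 80.0, 24.0, 150.0],
    ["step", 80.0, 38.0, 250.0],
    ["ramp", -80.0, 24.0, -50.0],
    ["ramp", -80.0, 38.0, -70.0],
    ["ramp", 80.0, 24.0, 150.0],
    ["ramp", 80.0, 38.0, 250.0],
]

leak_density_pa_pf = -6.1
cm_mean_pf = 2.45
cm_sd_pf = 0.1
cell_scale_cv = 0.2
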