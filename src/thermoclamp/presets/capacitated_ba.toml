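name = "capacitated_ba"
thermal_mode = "q10"
notes = "Capacitated sperm, divalent currents: nearly temperature-independent gating (-9.1 to -9.6 mV) and a blunted amplitude response; fast inactivation at heat. Density anchors are phenomenological."

v_half_cold = -9.1
v_half_hot = -9.6
k_cold = 15.0
k_hot = 15.0
q10_slow = 1.3
q10_steep = 1.5
t_threshold = 33.5
transition_center = 33.5
transition_width = 2.0
t_ref = 22.0
t_hot = 38.0

tau_ms = 25.0
h_inf = 0.4

v_rev_mv = 0.0
density_anchors = [
    ["step", -80.0, 24.0, -4.0],
    ["step", 80.0, 24.0, 12.0],
]

leak_density_pa_pf = 0.0
cm_mean_pf = 2.97
cm_sd_pf = 0.1
cell_scale_cv = 0.2
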