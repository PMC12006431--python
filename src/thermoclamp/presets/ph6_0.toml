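name = "pH6.0"
thermal_mode = "anchored"
notes = "Monovalent currents at intracellular pH 6.0: small inward currents, fast inactivation, small heat-induced midpoint shift. Slope factor is not printed ('shallow voltage dependence'); 20 mV keeps the G-V identified over the -140..+80 mV window."

v_half_cold = 43.2
v_half_hot = 24.6
k_cold = 20.0
k_hot = 20.0
q10_slow = 2.7
q10_steep = 5.01
t_threshold = 33.5
transition_center = 33.5
transition_width = 2.0
t_ref = 22.0
t_hot = 38.0

tau_ms = 25.0
h_inf = 0.35

v_rev_mv = 0.0
density_anchors = [
    ["ramp", -80.0, 24.0, -48.42],
    ["ramp", -80.0, 28.0, -50.01],
    ["ramp", -80.0, 32.0, -58.48],
    ["ramp", -80.0, 38.0, -78.56],
    ["ramp", 80.0, 24.0, 123.89],
    ["ramp", 80.0, 28.0, 134.47],
    ["ramp", 80.0, 32.0, 154.24],
    ["ramp", 80.0, 38.0, 196.79],
    ["step", -80.0, 24.0, -48.42],
    ["step", 80.0, 24.0, 123.89],
]

leak_density_pa_pf = -6.1
cm_mean_pf = 2.45
cm_sd_pf = 0.1
cell_scale_cv = 0.2
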