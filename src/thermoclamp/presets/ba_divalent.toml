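name = "ba_divalent"
thermal_mode = "q10"
notes = "Divalent (Ba2+) currents, the thermal-analysis condition: amplitude follows the exact piecewise-Q10 law (2.7 / 5.01, threshold 33.5 C) with voltage dependence frozen at the cold anchors. The printed -80 mV peak densities at 24 and 38 C are mutually consistent with this law to 0.06%. Divalent slope factor is not printed; 15 mV keeps the G-V identified. Baselines are subtracted in the source data, so the leak term is zero."

v_half_cold = 45.3
v_half_hot = -20.8
k_cold = 15.0
k_hot = 15.0
q10_slow = 2.7
q10_steep = 5.01
t_threshold = 33.5
transition_center = 33.5
transition_width = 2.0
t_ref = 22.0
t_hot = 38.0

tau_ms = "none"
h_inf = 1.0

v_rev_mv = 0.0
density_anchors = [
    ["step", -80.0, 24.0, -4.3],
    ["step", -80.0, 38.0, -22.8],
    ["step", 80.0, 24.0, 15.0],
    ["ramp", -80.0, 24.0, -4.3],
    ["ramp", 80.0, 24.0, 15.0],
]

leak_density_pa_pf = 0.0
cm_mean_pf = 2.53
cm_sd_pf = 0.1
cell_scale_cv = 0.2
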