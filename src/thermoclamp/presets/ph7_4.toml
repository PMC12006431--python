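name = "pH7.4"
thermal_mode = "anchored"
notes = "Monovalent (Cs+) currents, intracellular pH 7.4. Gating anchors from the measured G-V midpoints at 22 and 38 C; density anchors from the published -80/+80 mV ladders (ramp) and step-derived peak densities. Slope factor at 22 C is not printed and shares the 38 C value."

v_half_cold = -9.4
v_half_hot = -85.5
k_cold = 42.6
k_hot = 42.6
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
    ["ramp", -80.0, 24.0, -143.54],
    ["ramp", -80.0, 28.0, -162.2],
    ["ramp", -80.0, 32.0, -194.44],
    ["ramp", -80.0, 38.0, -271.81],
    ["ramp", 80.0, 24.0, 222.93],
    ["ramp", 80.0, 28.0, 245.84],
    ["ramp", 80.0, 32.0, 278.37],
    ["ramp", 80.0, 38.0, 340.85],
    ["step", -80.0, 24.0, -61.2],
    ["step", -80.0, 38.0, -220.3],
    ["step", 80.0, 24.0, 180.0],
]

leak_density_pa_pf = -6.1
cm_mean_pf = 2.45
cm_sd_pf = 0.1
cell_scale_cv = 0.2
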