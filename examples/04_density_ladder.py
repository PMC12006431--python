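"""Capacitance-normalized ramp densities across temperatures.

Simulates nine pH 7.4 cells and thirteen channel-null cells, samples each
voltage-ramp sweep at −80 mV and normalizes by membrane capacitance. The
wild-type inward density roughly doubles between 24 and 38 °C, while the
null cells show only the small temperature-insensitive residual leak —
the control that pins the heat response on the channel itself.
"""

import numpy as np

from thermoclamp import (RampProtocol, load_preset, ramp_density_at,
                         sample_cell, simulate_ramp_sweep)

for name, n_cells, seed in (("pH7.4", 9, 7), ("catsper_null", 13, 5)):
    preset = load_preset(name)
    cells = [sample_cell(preset, seed, i) for i in range(n_cells)]
    print(f"{name} (n = {n_cells}), density at -80 mV:")
    for t_c in (24.0, 28.0, 32.0, 38.0):
        dens = []
        for cell in cells:
            sweep, _hs = simulate_ramp_sweep(cell, RampProtocol(), t_c,
                                             preset=preset)
            dens.append(ramp_density_at(sweep, cell.cm_pf, voltage_mv=-80.0))
        dens = np.array(dens)
        sem = dens.std(ddof=1) / np.sqrt(len(dens))
        print(f"  {t_c:4.0f} °C: {dens.mean():8.2f} ± {sem:5.2f} pA/pF")
# pH 7.4 runs ≈ −144 → −272 pA/pF from 24 to 38 °C; the null cohort stays
# near −6 pA/pF at every temperature.
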