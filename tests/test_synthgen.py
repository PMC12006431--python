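"""Generator tests: protocols, cell sampling, sweep synthesis, determinism."""

import numpy as np
import pytest

from thermoclamp.model import load_preset, open_probability
from thermoclamp.synthgen import (
    RampProtocol,
    StepProtocol,
    TemperatureSchedule,
    generate_cohort,
    sample_cell,
    simulate_ramp_sweep,
    simulate_step_recording,
    simulate_thermal_series,
)
from thermoclamp.features import extract_amplitude, baseline_subtract


class TestProtocols:
    def test_step_defaults(self):
        p = StepProtocol()
        assert p.step_levels == tuple(float(v) for v in range(-140, 81, 20))
        assert p.n_samples == int(round((50 + 150 + 100) / 0.2))

    def test_step_levels_must_increase(self):
        with pytest.raises(ValueError):
            StepProtocol(step_levels=(0.0, -20.0))

    def test_ramp_voltage_at_400ms_is_minus20(self):
        p = RampProtocol()
        assert p.voltage_at(400.0) == pytest.approx(-20.0)
        v = p.command()
        t = p.times_ms()
        idx = int(np.argmin(np.abs(t - (p.pre_ms + 400.0))))
        assert v[idx] == pytest.approx(-20.0, abs=0.05)

    def test_schedule_bounds_and_interpolation(self):
        s = TemperatureSchedule.heating_ramp(24.0, 41.0)
        assert s.temperature_at(0.0) == 24.0
        assert s.temperature_range == (24.0, 41.0)
        with pytest.raises(ValueError):
            TemperatureSchedule(t_points=((0.0, 20.0), (10.0, 45.0)),
                                sweep_times=(0.0,))


class TestSampleCell:
    def test_degenerate_distributions(self, ph74):
        import dataclasses
        p = dataclasses.replace(ph74, cm_sd_pf=0.0, cell_scale_cv=0.0)
        c = sample_cell(p, 1, 0)
        assert c.cm_pf == p.cm_mean_pf
        assert c.scale == 1.0

    def test_determinism(self, ph74):
        a = sample_cell(ph74, 42, 3)
        b = sample_cell(ph74, 42, 3)
        assert a == b
        assert sample_cell(ph74, 42, 4) != a

    def test_capacitated_cm_mean_recovers_target(self, presets):
        cap = presets["capacitated_cs"]
        cms = np.array([sample_cell(cap, 123, i).cm_pf for i in range(10_000)])
        se = cms.std(ddof=1) / np.sqrt(len(cms))
        assert abs(cms.mean() - 2.77) < 3 * se + 0.01

    def test_scale_unit_mean(self, ph74):
        scales = np.array([sample_cell(ph74, 9, i).scale for i in range(20_000)])
        assert scales.mean() == pytest.approx(1.0, abs=0.01)


class TestStepRecording:
    def test_null_preset_is_pure_leak(self, null):
        cell = sample_cell(null, 1, 0)
        sweeps = simulate_step_recording(cell, StepProtocol(), 24.0, noise_sd=0.0,
                                         preset=null)
        for sw in sweeps:
            expected = cell.cm_pf * cell.scale * null.leak_density(sw.command_mv)
            np.testing.assert_allclose(sw.current_pa, expected, atol=1e-12)

    def test_tail_ratio_equals_po_ratio(self, ph74):
        # tail amplitudes are exactly proportional to Po(step level)
        cell = sample_cell(ph74, 2, 0)
        proto = StepProtocol()
        sweeps = simulate_step_recording(cell, proto, 38.0, noise_sd=0.0,
                                         preset=ph74)
        tails = {}
        for sw in sweeps:
            corr = baseline_subtract(sw, "holding")
            tails[sw.step_level_mv] = extract_amplitude(corr, "tail").value_pa
        g = ph74.effective_gating(38.0)
        got = tails[80.0] / tails[-140.0]
        want = open_probability(80.0, g) / open_probability(-140.0, g)
        assert got == pytest.approx(want, rel=1e-6)

    def test_cohort_peak_density_matches_anchor(self, ph74):
        # pH 7.4 cohort at 24 °C: step peak density at -80 mV ≈ -61.2 pA/pF
        cells = [sample_cell(ph74, 7, i) for i in range(9)]
        dens = []
        for cell in cells:
            sweeps = simulate_step_recording(cell, StepProtocol(), 24.0,
                                             noise_sd=5.0, preset=ph74)
            sw = next(s for s in sweeps if s.step_level_mv == -80.0)
            amp = extract_amplitude(baseline_subtract(sw, "holding"), "peak")
            dens.append(amp.value_pa / cell.cm_pf)
        assert np.mean(dens) == pytest.approx(-61.2, abs=2 * 6.3)

    def test_linearity_in_capacitance(self, ph74):
        import dataclasses
        cell = sample_cell(ph74, 3, 0)
        double = dataclasses.replace(cell, cm_pf=2 * cell.cm_pf)
        sw1 = simulate_step_recording(cell, StepProtocol(), 24.0, 0.0, ph74)[3]
        sw2 = simulate_step_recording(double, StepProtocol(), 24.0, 0.0, ph74)[3]
        np.testing.assert_allclose(sw2.current_pa, 2 * sw1.current_pa, rtol=1e-12)
        a1 = extract_amplitude(baseline_subtract(sw1, "holding"), "peak").value_pa
        a2 = extract_amplitude(baseline_subtract(sw2, "holding"), "peak").value_pa
        assert a2 / (2 * cell.cm_pf) == pytest.approx(a1 / cell.cm_pf, rel=1e-12)


class TestRampSweep:
    def test_null_sweep_equals_companion(self, null):
        cell = sample_cell(null, 4, 0)
        test, base = simulate_ramp_sweep(cell, RampProtocol(), 24.0, 0.0, null)
        np.testing.assert_allclose(test.current_pa, base.current_pa, atol=1e-12)

    def test_hot_ramp_density_matches_anchor(self, ph74):
        from thermoclamp.features import ramp_density_at
        cells = [sample_cell(ph74, 7, i) for i in range(9)]
        dens = []
        for cell in cells:
            sw, _ = simulate_ramp_sweep(cell, RampProtocol(), 38.0, 5.0, ph74)
            dens.append(ramp_density_at(sw, cell.cm_pf, voltage_mv=-80.0))
        assert np.mean(dens) == pytest.approx(-271.81, abs=2 * 19.97)


class TestThermalSeries:
    def test_flat_schedule_is_flat(self, ba):
        cell = sample_cell(ba, 5, 0)
        sched = TemperatureSchedule(t_points=((0.0, 24.0), (100.0, 24.0)),
                                    sweep_times=tuple(range(0, 100, 10)))
        sweeps = simulate_thermal_series(cell, RampProtocol(), sched, 0.0, ba)
        tests = [s for s in sweeps if not s.is_baseline]
        vals = [s.current_pa[3000] for s in tests]
        assert np.ptp(vals) < 1e-9

    def test_heat_then_cool_reversible(self, ba):
        cell = sample_cell(ba, 5, 1)
        sched = TemperatureSchedule(
            t_points=((0.0, 24.0), (100.0, 40.0), (200.0, 24.0)),
            sweep_times=(0.0, 50.0, 100.0, 150.0, 200.0),
        )
        sweeps = simulate_thermal_series(cell, RampProtocol(), sched, 0.0, ba)
        tests = [s for s in sweeps if not s.is_baseline]
        # 0 vs 200 s (24 °C) and 50 vs 150 s (32 °C) must match exactly
        np.testing.assert_allclose(tests[0].current_pa, tests[4].current_pa)
        np.testing.assert_allclose(tests[1].current_pa, tests[3].current_pa)

    def test_threshold_not_covered_warns_in_metadata(self, ba):
        cell = sample_cell(ba, 5, 2)
        sched = TemperatureSchedule(t_points=((0.0, 24.0), (50.0, 30.0)),
                                    sweep_times=(0.0, 10.0, 20.0, 30.0, 40.0, 50.0))
        sweeps = simulate_thermal_series(cell, RampProtocol(), sched, 0.0, ba)
        assert all("warning" in s.meta for s in sweeps)


class TestGenerateCohort:
    def test_empty_cohort_valid(self, tmp_path):
        from thermoclamp.traceio import read_dataset
        path = generate_cohort("pH7.4", 0, [{"kind": "step", "temperatures": [24.0]}],
                               seed=1, out_path=tmp_path / "empty")
        sweeps, manifest = read_dataset(path)
        assert sweeps == [] and manifest.cells == []

    def test_same_seed_byte_identical(self, tmp_path):
        spec = [{"kind": "ramp", "temperatures": [24.0, 38.0]}]
        p1 = generate_cohort("pH6.0", 2, spec, seed=5, out_path=tmp_path / "a")
        p2 = generate_cohort("pH6.0", 2, spec, seed=5, out_path=tmp_path / "b")
        f1 = sorted(f.relative_to(p1) for f in p1.rglob("*") if f.is_file())
        f2 = sorted(f.relative_to(p2) for f in p2.rglob("*") if f.is_file())
        assert f1 == f2
        for rel in f1:
            assert (p1 / rel).read_bytes() == (p2 / rel).read_bytes()

    def test_refuses_nonempty_path(self, tmp_path):
        out = tmp_path / "d"
        out.mkdir()
        (out / "x").write_text("hi")
        with pytest.raises(FileExistsError):
            generate_cohort("pH7.4", 1, [{"kind": "ramp", "temperatures": [24.0]}],
                            seed=1, out_path=out)

    def test_thermal_cohort_file_count(self, tmp_path):
        from thermoclamp.traceio import read_dataset
        path = generate_cohort("ba_divalent", 2, [{"kind": "thermal"}], seed=3,
                               out_path=tmp_path / "th")
        sweeps, manifest = read_dataset(path)
        # 18 scheduled temperatures × (test + companion) per cell
        assert len(sweeps) == 2 * 18 * 2
        assert len(manifest.sweep_files) == len(sweeps)
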