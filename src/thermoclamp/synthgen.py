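"""Stimulus protocols and stochastic synthesis of whole-cell recordings.

The generator emulates the study conditions of divalent-free whole-cell sperm
recordings: voltage-step families with tail segments, voltage ramps with an
HS-solution baseline companion, and slow temperature ramps (22–41 °C) during
which ramp sweeps are delivered repeatedly. Temperature is treated as
constant within a single sweep (sweeps last ≤ ~1 s; bath ramps are slow).

All randomness flows from explicit integer seeds; regenerating a cohort with
the same seed is bit-identical. Capacitance transients and seal artifacts are
not simulated (datasets correspond to recordings after graphical artifact
removal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import ConditionPreset, load_preset, open_probability
from .traceio import SweepRecord

__all__ = [
    "StepProtocol",
    "RampProtocol",
    "TemperatureSchedule",
    "SyntheticCell",
    "sample_cell",
    "simulate_step_recording",
    "simulate_ramp_sweep",
    "simulate_thermal_series",
    "generate_cohort",
    "DEFAULT_NOISE_SD_PA",
]

DEFAULT_NOISE_SD_PA = 5.0  # ~2 pA/pF at typical Cm; matches published SEM magnitudes
DEACTIVATION_TAU_MS = 2.0  # tail deactivation; well resolved at dt = 0.2 ms
CM_BOUNDS_PF = (2.0, 3.5)


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step family: hold, step to each level, repolarize to a tail potential."""

    holding_mv: float = 0.0
    step_levels: tuple[float, ...] = tuple(float(v) for v in range(-140, 81, 20))
    pre_ms: float = 50.0
    step_ms: float = 150.0
    tail_ms: float = 100.0
    tail_mv: float = -100.0
    dt_ms: float = 0.2

    def __post_init__(self) -> None:
        if len(self.step_levels) < 1 or np.any(np.diff(self.step_levels) <= 0):
            raise ValueError("step_levels must be strictly increasing")
        if min(self.pre_ms, self.step_ms, self.tail_ms, self.dt_ms) <= 0:
            raise ValueError("durations and dt must be > 0")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.tail_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.total_ms / self.dt_ms))

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def command(self, level_mv: float) -> np.ndarray:
        t = self.times_ms()
        v = np.full_like(t, self.holding_mv)
        in_step = (t >= self.pre_ms) & (t < self.pre_ms + self.step_ms)
        v[in_step] = level_mv
        v[t >= self.pre_ms + self.step_ms] = self.tail_mv
        return v


@dataclass(frozen=True)
class RampProtocol:
    """Linear voltage ramp preceded by a short holding segment."""

    v_start_mv: float = -100.0
    v_end_mv: float = 100.0
    duration_ms: float = 1000.0
    holding_mv: float = 0.0
    pre_ms: float = 50.0
    dt_ms: float = 0.2

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.dt_ms <= 0 or self.pre_ms <= 0:
            raise ValueError("durations and dt must be > 0")
        if self.v_end_mv == self.v_start_mv:
            raise ValueError("ramp must span a nonzero voltage range")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.duration_ms

    @property
    def n_samples(self) -> int:
        return int(round(self.total_ms / self.dt_ms))

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def voltage_at(self, t_since_onset_ms) -> np.ndarray:
        """Command voltage as a function of time since ramp onset (ms)."""
        frac = np.clip(np.asarray(t_since_onset_ms, dtype=float) / self.duration_ms, 0, 1)
        return self.v_start_mv + frac * (self.v_end_mv - self.v_start_mv)

    def command(self) -> np.ndarray:
        t = self.times_ms()
        v = np.full_like(t, self.holding_mv)
        on = t >= self.pre_ms
        v[on] = self.voltage_at(t[on] - self.pre_ms)
        return v


@dataclass(frozen=True)
class TemperatureSchedule:
    """Piecewise-linear bath temperature vs time, with sweep delivery times.

    ``t_points`` are (time_s, °C) breakpoints, e.g. a heating leg 24→41 °C and
    an optional cooling return; ``sweep_times`` (s) mark when ramp sweeps are
    delivered.
    """

    t_points: tuple[tuple[float, float], ...]
    sweep_times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = [p[0] for p in self.t_points]
        if len(self.t_points) < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("t_points must have >= 2 strictly increasing times")
        for _, temp in self.t_points:
            if not 22.0 <= temp <= 43.0:
                raise ValueError(f"schedule temperature {temp} outside 22–43 °C")
        lo, hi = times[0], times[-1]
        for s in self.sweep_times:
            if not lo <= s <= hi:
                raise ValueError(f"sweep time {s} outside schedule span")

    def temperature_at(self, time_s) -> np.ndarray:
        times = np.array([p[0] for p in self.t_points])
        temps = np.array([p[1] for p in self.t_points])
        out = np.interp(np.asarray(time_s, dtype=float), times, temps)
        return float(out) if np.isscalar(time_s) else out

    @property
    def temperature_range(self) -> tuple[float, float]:
        temps = np.array([self.temperature_at(s) for s in self.sweep_times])
        return float(temps.min()), float(temps.max())

    @classmethod
    def heating_ramp(cls, t_start_c: float = 24.0, t_end_c: float = 41.0,
                     rate_c_per_s: float = 0.1, sweep_every_c: float = 1.0
                     ) -> "TemperatureSchedule":
        """Monotone heating leg with one sweep per ``sweep_every_c`` degree."""
        span = t_end_c - t_start_c
        duration = span / rate_c_per_s
        n = int(math.floor(span / sweep_every_c)) + 1
        sweep_times = tuple(i * sweep_every_c / rate_c_per_s for i in range(n))
        return cls(t_points=((0.0, t_start_c), (duration, t_end_c)),
                   sweep_times=sweep_times)


@dataclass(frozen=True)
class SyntheticCell:
    """One simulated cell: capacitance, amplitude scale, condition, private seed."""

    cell_id: str
    cm_pf: float
    scale: float
    condition: str
    seed: int

    def __post_init__(self) -> None:
        if self.cm_pf <= 0 or self.scale <= 0:
            raise ValueError("cm_pf and scale must be > 0")


def sample_cell(preset: ConditionPreset, rng_seed: int, index: int) -> SyntheticCell:
    """Draw one cell: Cm ~ truncated normal, scale ~ unit-mean lognormal.

    Fully determined by ``(preset, rng_seed, index)``.
    """
    rng = np.random.default_rng([int(rng_seed), int(index)])
    lo, hi = CM_BOUNDS_PF
    if preset.cm_sd_pf == 0:
        cm = preset.cm_mean_pf
    else:
        a = (lo - preset.cm_mean_pf) / preset.cm_sd_pf
        b = (hi - preset.cm_mean_pf) / preset.cm_sd_pf
        cm = float(stats.truncnorm.rvs(a, b, loc=preset.cm_mean_pf,
                                       scale=preset.cm_sd_pf, random_state=rng))
    cv = preset.cell_scale_cv
    if cv == 0:
        scale = 1.0
    else:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        # unit mean so that cohort-mean densities target the preset anchors
        scale = float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))
    seed = int(rng.integers(0, 2**31 - 1))
    return SyntheticCell(cell_id=f"{preset.name}-c{index:03d}", cm_pf=cm,
                         scale=scale, condition=preset.name, seed=seed)


def _sweep_rng(cell: SyntheticCell, tag: int) -> np.random.Generator:
    return np.random.default_rng([cell.seed, tag])


def _noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def simulate_step_recording(cell: SyntheticCell, protocol: StepProtocol,
                            t_c: float, noise_sd: float = DEFAULT_NOISE_SD_PA,
                            preset: ConditionPreset | None = None,
                            sweep_tag: int = 0) -> list[SweepRecord]:
    """One step family at a fixed bath temperature: one sweep per level.

    Within the step the gated current inactivates from its instantaneous peak;
    at the step→tail transition the conductance reflects the open probability
    reached at the step level and deactivates mono-exponentially (τ = 2 ms) to
    zero, so the tail amplitude is exactly proportional to Po(step level).
    """
    if preset is None:
        preset = load_preset(cell.condition)
    gating = preset.effective_gating(t_c)
    vr = preset.permeation.v_rev_mv
    t = protocol.times_ms()
    pre_end = protocol.pre_ms
    step_end = protocol.pre_ms + protocol.step_ms
    in_pre = t < pre_end
    in_step = (t >= pre_end) & (t < step_end)
    in_tail = t >= step_end
    g_tail = preset._conductance_at("step", int(np.sign(protocol.tail_mv - vr)) or -1, t_c)

    sweeps = []
    for i, level in enumerate(protocol.step_levels):
        dens = np.empty_like(t)
        dens[in_pre] = preset.current_density(protocol.holding_mv, t_c, 0.0, "step")
        elapsed = t[in_step] - pre_end
        h = preset.inactivation.survival(elapsed)
        dens[in_step] = (preset.gated_density(level, t_c, 0.0, "step") * h
                         + preset.leak_density(level))
        po_step = open_probability(level, gating)
        h_end = float(preset.inactivation.survival(protocol.step_ms))
        decay = np.exp(-(t[in_tail] - step_end) / DEACTIVATION_TAU_MS)
        dens[in_tail] = (po_step * (protocol.tail_mv - vr) * g_tail * h_end * decay
                         + preset.leak_density(protocol.tail_mv))
        rng = _sweep_rng(cell, 1000 * sweep_tag + i)
        current = cell.cm_pf * cell.scale * dens + _noise(rng, t.size, noise_sd)
        sweeps.append(SweepRecord(
            sweep_id=f"{cell.cell_id}-step{sweep_tag}-{int(level):+d}mV",
            cell_id=cell.cell_id, condition=cell.condition, protocol="step",
            step_level_mv=float(level), temperature_c=float(t_c),
            dt_ms=protocol.dt_ms, time_ms=t.copy(),
            command_mv=protocol.command(level), current_pa=current,
            is_baseline=False, cm_pf=cell.cm_pf,
            meta={"pre_ms": protocol.pre_ms, "step_ms": protocol.step_ms,
                  "tail_ms": protocol.tail_ms, "tail_mv": protocol.tail_mv,
                  "holding_mv": protocol.holding_mv},
        ))
    return sweeps


def simulate_ramp_sweep(cell: SyntheticCell, protocol: RampProtocol, t_c: float,
                        noise_sd: float = DEFAULT_NOISE_SD_PA,
                        preset: ConditionPreset | None = None,
                        sweep_tag: int = 0) -> tuple[SweepRecord, SweepRecord]:
    """One ramp sweep plus its HS-baseline companion (leak only, gating off).

    Ramp currents are generated at the peak phase (inactivation clock not
    running), matching how the anchored ramp densities were measured.
    """
    if preset is None:
        preset = load_preset(cell.condition)
    t = protocol.times_ms()
    v = protocol.command()
    dens = preset.gated_density(v, t_c, 0.0, "ramp") + preset.leak_density(v)
    leak = preset.leak_density(v)
    meta = {"pre_ms": protocol.pre_ms, "ramp_ms": protocol.duration_ms,
            "v_start_mv": protocol.v_start_mv, "v_end_mv": protocol.v_end_mv,
            "holding_mv": protocol.holding_mv}
    rng = _sweep_rng(cell, 2_000_000 + 2 * sweep_tag)
    rng_b = _sweep_rng(cell, 2_000_001 + 2 * sweep_tag)
    test = SweepRecord(
        sweep_id=f"{cell.cell_id}-ramp{sweep_tag}", cell_id=cell.cell_id,
        condition=cell.condition, protocol="ramp", step_level_mv=None,
        temperature_c=float(t_c), dt_ms=protocol.dt_ms, time_ms=t.copy(),
        command_mv=v, current_pa=cell.cm_pf * cell.scale * dens
        + _noise(rng, t.size, noise_sd),
        is_baseline=False, cm_pf=cell.cm_pf, meta=dict(meta),
    )
    base = SweepRecord(
        sweep_id=f"{cell.cell_id}-ramp{sweep_tag}-hs", cell_id=cell.cell_id,
        condition=cell.condition, protocol="ramp", step_level_mv=None,
        temperature_c=float(t_c), dt_ms=protocol.dt_ms, time_ms=t.copy(),
        command_mv=v.copy(), current_pa=cell.cm_pf * cell.scale * leak
        + _noise(rng_b, t.size, noise_sd),
        is_baseline=True, cm_pf=cell.cm_pf, meta=dict(meta),
    )
    return test, base


def simulate_thermal_series(cell: SyntheticCell, ramp: RampProtocol,
                            schedule: TemperatureSchedule,
                            noise_sd: float = DEFAULT_NOISE_SD_PA,
                            preset: ConditionPreset | None = None
                            ) -> list[SweepRecord]:
    """Ramp sweeps delivered along a temperature schedule (plus companions).

    The model is memoryless in temperature, so cooling legs retrace heating
    values exactly at zero noise. If the schedule does not bracket the
    preset's thermal threshold, a warning is recorded in each sweep's
    metadata rather than raised.
    """
    if preset is None:
        preset = load_preset(cell.condition)
    lo, hi = schedule.temperature_range
    warn = None
    if not (lo < preset.gating.t_threshold < hi):
        warn = (f"schedule {lo:.1f}-{hi:.1f} C does not bracket the thermal "
                f"threshold {preset.gating.t_threshold:.1f} C")
    sweeps: list[SweepRecord] = []
    for j, time_s in enumerate(schedule.sweep_times):
        t_c = schedule.temperature_at(time_s)
        test, base = simulate_ramp_sweep(cell, ramp, t_c, noise_sd, preset,
                                         sweep_tag=10_000 + j)
        for sw in (test, base):
            sw.meta["schedule_time_s"] = float(time_s)
            if warn:
                sw.meta["warning"] = warn
        sweeps += [test, base]
    return sweeps


def generate_cohort(preset_name: str, n_cells: int, protocols, seed: int,
                    out_path, noise_sd: float = DEFAULT_NOISE_SD_PA,
                    overwrite: bool = False):
    """Simulate a cohort and write it as a dataset directory.

    ``protocols`` is a sequence of protocol specs, each a dict with a
    ``kind`` key:

    * ``{"kind": "step", "temperatures": [...], "protocol": StepProtocol?}``
    * ``{"kind": "ramp", "temperatures": [...], "protocol": RampProtocol?}``
    * ``{"kind": "thermal", "schedule": TemperatureSchedule?,
         "protocol": RampProtocol?}``

    Returns the dataset path. Deterministic for fixed seed.
    """
    from .traceio import DatasetManifest, write_dataset

    preset = load_preset(preset_name)
    cells = [sample_cell(preset, seed, i) for i in range(n_cells)]
    sweeps: list[SweepRecord] = []
    for cell in cells:
        tag = 0
        for spec in protocols:
            kind = spec["kind"]
            if kind == "step":
                proto = spec.get("protocol") or StepProtocol()
                for t_c in spec["temperatures"]:
                    sweeps += simulate_step_recording(cell, proto, t_c, noise_sd,
                                                      preset, sweep_tag=tag)
                    tag += 1
            elif kind == "ramp":
                proto = spec.get("protocol") or RampProtocol()
                for t_c in spec["temperatures"]:
                    test, base = simulate_ramp_sweep(cell, proto, t_c, noise_sd,
                                                     preset, sweep_tag=tag)
                    sweeps += [test, base]
                    tag += 1
            elif kind == "thermal":
                proto = spec.get("protocol") or RampProtocol()
                schedule = spec.get("schedule") or TemperatureSchedule.heating_ramp()
                sweeps += simulate_thermal_series(cell, proto, schedule,
                                                 noise_sd, preset)
                tag += 1
            else:
                raise ValueError(f"unknown protocol kind {kind!r}")
    counts = {c.cell_id: 0 for c in cells}
    for sw in sweeps:
        counts[sw.cell_id] += 1
    manifest = DatasetManifest(
        preset_name=preset_name, preset=preset, seed=int(seed),
        cells=[{"cell_id": c.cell_id, "cm_pf": c.cm_pf, "scale": c.scale,
                "n_sweeps": counts[c.cell_id]} for c in cells],
        notes={"noise_sd_pa": noise_sd,
               "assumption": "temperature constant within each sweep"},
    )
    return write_dataset(sweeps, manifest, out_path, overwrite=overwrite)
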