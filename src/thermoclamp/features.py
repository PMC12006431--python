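"""Sweep-level amplitude extraction and normalization.

These are the quantities read off whole-cell recordings: baseline-corrected
peak / steady-state / tail amplitudes, capacitance-normalized current
densities, I-V curves aggregated over cells, ramp samples at a target voltage
or time, and current-vs-temperature series for the Arrhenius analysis.

Window conventions (all configurable): the peak search skips the first
``PEAK_BLANK_MS`` of each step (residual capacitive edge in real data), the
steady state is the mean of the last tenth of the step, and the tail is the
signed extremum within ``TAIL_WINDOW_MS`` after the step→tail transition
minus the tail's own steady level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thermal import ThermalSeries
from .traceio import DatasetManifest, SweepRecord

__all__ = [
    "AmplitudeMeasure",
    "IVCurve",
    "baseline_subtract",
    "extract_amplitude",
    "to_density",
    "iv_from_steps",
    "ramp_density_at",
    "thermal_series_from_sweeps",
    "FeatureError",
]

PEAK_BLANK_MS = 2.0
TAIL_WINDOW_MS = 10.0
STEADY_FRACTION = 0.1
MIN_HOLDING_MS = 10.0


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class AmplitudeMeasure:
    kind: str  # "peak" | "steady" | "tail"
    value_pa: float
    window_ms: tuple[float, float]
    step_level_mv: float | None


@dataclass(frozen=True)
class IVCurve:
    """Mean current density vs step voltage at a stated measure, with SEM."""

    v_mv: np.ndarray
    density_pa_pf: np.ndarray
    sem: np.ndarray
    measure: str
    temperature_c: float
    n_cells: int


def baseline_subtract(sweep: SweepRecord, mode: str = "holding",
                      companion: SweepRecord | None = None) -> SweepRecord:
    """Return a baseline-corrected copy of the sweep.

    ``mode="holding"`` subtracts the mean current of the pre-stimulus holding
    segment (requires >= 10 ms of holding); ``mode="companion"`` subtracts an
    HS-solution companion sweep sample-wise.
    """
    if mode == "holding":
        pre_ms = float(sweep.meta.get("pre_ms", 0.0))
        if pre_ms < MIN_HOLDING_MS:
            raise FeatureError(
                f"{sweep.sweep_id}: holding segment {pre_ms} ms < {MIN_HOLDING_MS} ms"
            )
        sel = sweep.time_ms < pre_ms
        return sweep.copy_with_current(sweep.current_pa - sweep.current_pa[sel].mean())
    if mode == "companion":
        if companion is None:
            raise FeatureError(f"{sweep.sweep_id}: companion sweep required")
        if len(companion.current_pa) != len(sweep.current_pa):
            raise FeatureError(f"{sweep.sweep_id}: companion length mismatch")
        return sweep.copy_with_current(sweep.current_pa - companion.current_pa)
    raise FeatureError(f"unknown baseline mode {mode!r}")


def _segment(sweep: SweepRecord):
    pre = float(sweep.meta["pre_ms"])
    step = float(sweep.meta["step_ms"])
    return pre, pre + step


def extract_amplitude(sweep: SweepRecord, kind: str, v_rev_mv: float = 0.0
                      ) -> AmplitudeMeasure:
    """Peak, steady-state, or tail amplitude of a baseline-corrected step sweep.

    The peak is the signed extremum matching the expected polarity (inward
    below the reversal potential); the tail is referenced to the tail's own
    steady level, so it isolates the deactivating component.
    """
    if sweep.protocol != "step":
        raise FeatureError(f"{sweep.sweep_id}: amplitude extraction needs a step sweep")
    t = sweep.time_ms
    cur = sweep.current_pa
    step_start, step_end = _segment(sweep)
    level = sweep.step_level_mv

    if kind == "peak":
        lo = step_start + PEAK_BLANK_MS
        sel = (t >= lo) & (t < step_end)
        if sel.sum() < 5:
            raise FeatureError(f"{sweep.sweep_id}: peak window shorter than 5 samples")
        seg = cur[sel]
        if level < v_rev_mv:
            value = float(seg.min())
        elif level > v_rev_mv:
            value = float(seg.max())
        else:
            value = float(seg[np.argmax(np.abs(seg))])
        return AmplitudeMeasure("peak", value, (lo, step_end), level)

    if kind == "steady":
        lo = step_end - STEADY_FRACTION * (step_end - step_start)
        sel = (t >= lo) & (t < step_end)
        if sel.sum() < 5:
            raise FeatureError(f"{sweep.sweep_id}: steady window shorter than 5 samples")
        return AmplitudeMeasure("steady", float(cur[sel].mean()), (lo, step_end), level)

    if kind == "tail":
        tail_end = t[-1] + sweep.dt_ms
        hi = step_end + TAIL_WINDOW_MS
        sel = (t >= step_end) & (t < hi)
        if sel.sum() < 5:
            raise FeatureError(f"{sweep.sweep_id}: tail window shorter than 5 samples")
        steady_lo = tail_end - STEADY_FRACTION * (tail_end - step_end)
        tail_steady = float(cur[(t >= steady_lo)].mean())
        seg = cur[sel] - tail_steady
        tail_mv = float(sweep.meta.get("tail_mv", -100.0))
        if tail_mv < v_rev_mv:
            value = float(seg.min())
        else:
            value = float(seg.max())
        return AmplitudeMeasure("tail", value, (step_end, hi), level)

    raise FeatureError(f"unknown measure kind {kind!r}")


def to_density(amp_pa: float, cm_pf: float) -> float:
    """Capacitance-normalized current density (pA/pF)."""
    if cm_pf <= 0:
        raise FeatureError(f"cm_pf must be > 0, got {cm_pf}")
    return amp_pa / cm_pf


def iv_from_steps(sweeps, manifest: DatasetManifest, measure: str = "peak",
                  temperature_c: float | None = None,
                  baseline: str = "holding", v_rev_mv: float = 0.0) -> IVCurve:
    """I-V curve: per-voltage mean density ± SEM across cells.

    Step sweeps are grouped by cell; every cell must have been stimulated
    with the same step levels.
    """
    chosen = [s for s in sweeps if s.protocol == "step" and not s.is_baseline]
    if temperature_c is not None:
        chosen = [s for s in chosen if abs(s.temperature_c - temperature_c) < 0.5]
    if not chosen:
        raise FeatureError("no step sweeps selected")
    by_cell: dict[str, dict[float, float]] = {}
    for sw in chosen:
        corr = baseline_subtract(sw, baseline)
        amp = extract_amplitude(corr, measure, v_rev_mv)
        cm = manifest.cm_for(sw.cell_id)
        by_cell.setdefault(sw.cell_id, {})[sw.step_level_mv] = to_density(amp.value_pa, cm)
    levels = sorted(next(iter(by_cell.values())))
    for cid, d in by_cell.items():
        if sorted(d) != levels:
            raise FeatureError(f"cell {cid}: inconsistent step levels")
    dens = np.array([[by_cell[cid][v] for v in levels] for cid in sorted(by_cell)])
    n = dens.shape[0]
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(levels))
    t_c = chosen[0].temperature_c if temperature_c is None else temperature_c
    return IVCurve(np.array(levels, dtype=float), mean, sem, measure, float(t_c), n)


def ramp_density_at(sweep: SweepRecord, cm_pf: float,
                    voltage_mv: float | None = None, time_ms: float | None = None,
                    baseline: str = "holding",
                    companion: SweepRecord | None = None) -> float:
    """Current density sampled from a ramp sweep at a voltage or a time target.

    Time targets are measured from ramp onset. Voltage targets are resolved
    through the recorded command trace (nearest sample within the ramp), so
    imported recordings with non-ideal commands still work.
    """
    if sweep.protocol != "ramp":
        raise FeatureError(f"{sweep.sweep_id}: ramp sweep required")
    if (voltage_mv is None) == (time_ms is None):
        raise FeatureError("specify exactly one of voltage_mv / time_ms")
    corr = baseline_subtract(sweep, baseline, companion)
    pre_ms = float(sweep.meta.get("pre_ms", 0.0))
    on = corr.time_ms >= pre_ms
    t_on = corr.time_ms[on] - pre_ms
    v_on = corr.command_mv[on]
    i_on = corr.current_pa[on]
    if voltage_mv is not None:
        if not (min(v_on) <= voltage_mv <= max(v_on)):
            raise FeatureError(f"target {voltage_mv} mV outside ramp span")
        idx = int(np.argmin(np.abs(v_on - voltage_mv)))
    else:
        if not (t_on[0] <= time_ms <= t_on[-1]):
            raise FeatureError(f"target {time_ms} ms outside ramp duration")
        idx = int(np.argmin(np.abs(t_on - time_ms)))
    return to_density(float(i_on[idx]), cm_pf)


def thermal_series_from_sweeps(sweeps, cm_pf: float | None = None,
                               time_ms: float = 400.0,
                               voltage_mv: float | None = None,
                               baseline: str = "companion") -> ThermalSeries:
    """Current-vs-temperature series from one cell's thermal-ramp sweeps.

    Pairs each ramp sweep's bath temperature with its current sampled at the
    fixed target (default 400 ms after ramp onset, ≈ −20 mV under the default
    ramp). Baseline companions are matched to test sweeps by position.
    Duplicate temperatures are collapsed by mean; the series is ordered by
    temperature. With ``cm_pf`` the series is in pA/pF, otherwise pA.
    """
    tests = [s for s in sweeps if s.protocol == "ramp" and not s.is_baseline]
    bases = {s.sweep_id: s for s in sweeps if s.protocol == "ramp" and s.is_baseline}
    if len(tests) < 4:
        raise FeatureError("need >= 4 ramp sweeps for a thermal series")
    cells = {s.cell_id for s in tests}
    if len(cells) != 1:
        raise FeatureError(f"thermal series mixes cells: {sorted(cells)}")
    pairs = []
    for sw in tests:
        companion = bases.get(sw.sweep_id + "-hs")
        if baseline == "companion" and companion is None:
            raise FeatureError(f"{sw.sweep_id}: no HS companion found")
        val = ramp_density_at(sw, cm_pf if cm_pf else 1.0,
                              voltage_mv=voltage_mv,
                              time_ms=None if voltage_mv is not None else time_ms,
                              baseline=baseline, companion=companion)
        pairs.append((sw.temperature_c, val))
    by_temp: dict[float, list[float]] = {}
    for t_c, val in pairs:
        by_temp.setdefault(round(t_c, 6), []).append(val)
    temps = np.array(sorted(by_temp))
    vals = np.array([np.mean(by_temp[t]) for t in temps])
    rule = (f"{voltage_mv} mV" if voltage_mv is not None else f"{time_ms} ms")
    return ThermalSeries(
        temperature_c=temps, current=vals, cell_id=next(iter(cells)),
        sample_rule=rule, units="pA/pF" if cm_pf else "pA",
    )
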