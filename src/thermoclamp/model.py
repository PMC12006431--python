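"""Deterministic biophysical model of a temperature- and voltage-gated channel.

The model composes four ingredients into a current density (pA/pF):

* a two-state Boltzmann open probability ``Po(V) = 1/(1 + exp((V1/2 - V)/k))``,
* a temperature-dependent gating profile that moves ``V1/2`` (and ``k``)
  between a cold and a hot anchor,
* a conductance amplitude that grows with temperature — either as an exact
  piecewise-Q10 law around a thermal threshold, or interpolated through
  measured current-density anchors,
* an ohmic, temperature-insensitive residual leak.

Sign convention: inward current negative, potentials in mV, current densities
in pA/pF, temperatures in degrees Celsius (Kelvin appears only inside the
Arrhenius analysis in :mod:`thermoclamp.thermal`).

Condition presets calibrated to published whole-cell sperm recordings are
shipped as package data and loaded with :func:`load_preset`.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BoltzmannGating",
    "ThermalGatingProfile",
    "InactivationParams",
    "DensityAnchor",
    "PermeationAnchors",
    "ConditionPreset",
    "open_probability",
    "v_half_at_temperature",
    "thermal_conductance_scale",
    "inactivation_time_course",
    "current_density_model",
    "load_preset",
    "available_presets",
    "preset_to_toml",
    "preset_from_toml",
    "PresetError",
]

PRESET_NAMES = (
    "pH7.4",
    "pH6.0",
    "spermine",
    "capacitated_cs",
    "ba_divalent",
    "capacitated_ba",
    "catsper_null",
)

_PRESET_FILES = {
    "pH7.4": "ph7_4.toml",
    "pH6.0": "ph6_0.toml",
    "spermine": "spermine.toml",
    "capacitated_cs": "capacitated_cs.toml",
    "ba_divalent": "ba_divalent.toml",
    "capacitated_ba": "capacitated_ba.toml",
    "catsper_null": "catsper_null.toml",
}


class PresetError(ValueError):
    """Invalid or uncalibratable condition preset."""


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class BoltzmannGating:
    """Two-state voltage gating: midpoint ``v_half_mv`` and slope factor ``slope_k_mv``.

    The slope factor is the voltage change (mV) producing an e-fold change in
    the opening odds; it must be positive.
    """

    v_half_mv: float
    slope_k_mv: float

    def __post_init__(self) -> None:
        _check_finite("BoltzmannGating", self.v_half_mv, self.slope_k_mv)
        if self.slope_k_mv <= 0:
            raise ValueError(f"slope factor must be > 0, got {self.slope_k_mv}")

    def open_probability(self, v_mv):
        return open_probability(v_mv, self)


def open_probability(v_mv, gating: BoltzmannGating):
    """Boltzmann open probability, strictly increasing in voltage, in (0, 1)."""
    v = np.asarray(v_mv, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("open_probability: non-finite voltage")
    with np.errstate(over="ignore"):
        po = 1.0 / (1.0 + np.exp((gating.v_half_mv - v) / gating.slope_k_mv))
    return float(po) if np.isscalar(v_mv) else po


def _sigmoid(z):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class ThermalGatingProfile:
    """Temperature dependence of the Boltzmann gating and of the conductance.

    ``v_half_cold``/``k_cold`` apply at the reference temperature ``t_ref``
    (default 22 °C) and ``v_half_hot``/``k_hot`` at ``t_hot`` (default 38 °C,
    the two temperatures at which G-V curves were measured). In between,
    ``v_half_at`` follows a logistic transition centred on
    ``transition_center`` with width ``transition_width``, affinely rescaled
    so it passes through both anchors exactly.

    ``q10_slow``/``q10_steep`` and ``t_threshold`` define the piecewise-Q10
    conductance amplitude law used by :func:`thermal_conductance_scale`.
    """

    v_half_cold: float
    v_half_hot: float
    k_cold: float
    k_hot: float
    q10_slow: float
    q10_steep: float
    t_threshold: float
    transition_center: float = 33.5
    transition_width: float = 2.0
    t_ref: float = 22.0
    t_hot: float = 38.0

    def __post_init__(self) -> None:
        _check_finite(
            "ThermalGatingProfile",
            self.v_half_cold, self.v_half_hot, self.k_cold, self.k_hot,
            self.q10_slow, self.q10_steep, self.t_threshold,
            self.transition_center, self.transition_width, self.t_ref, self.t_hot,
        )
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")
        if self.q10_slow <= 0 or self.q10_steep <= 0:
            raise ValueError("Q10 values must be > 0")
        if self.k_cold <= 0 or self.k_hot <= 0:
            raise ValueError("slope factors must be > 0")
        if self.t_hot <= self.t_ref:
            raise ValueError("t_hot must exceed t_ref")

    def _blend(self, t_c):
        # Logistic interpolant normalized so blend(t_ref) = 0 and blend(t_hot) = 1.
        z = (np.asarray(t_c, dtype=float) - self.transition_center) / self.transition_width
        s = _sigmoid(z)
        s0 = float(_sigmoid((self.t_ref - self.transition_center) / self.transition_width))
        s1 = float(_sigmoid((self.t_hot - self.transition_center) / self.transition_width))
        return (s - s0) / (s1 - s0)

    def v_half_at(self, t_c):
        u = self._blend(t_c)
        out = self.v_half_cold + (self.v_half_hot - self.v_half_cold) * u
        return float(out) if np.isscalar(t_c) else out

    def k_at(self, t_c):
        u = self._blend(t_c)
        out = self.k_cold + (self.k_hot - self.k_cold) * u
        return float(out) if np.isscalar(t_c) else out

    def gating_at(self, t_c: float) -> BoltzmannGating:
        return BoltzmannGating(self.v_half_at(float(t_c)), self.k_at(float(t_c)))

    def conductance_scale(self, t_c):
        return thermal_conductance_scale(t_c, self)


def v_half_at_temperature(t_c, profile: ThermalGatingProfile):
    """Midpoint voltage at temperature ``t_c`` (anchor-exact logistic interpolation)."""
    if np.isscalar(t_c) and not math.isfinite(float(t_c)):
        raise ValueError("non-finite temperature")
    return profile.v_half_at(t_c)


def thermal_conductance_scale(t_c, profile: ThermalGatingProfile):
    """Piecewise-Q10 amplitude factor, 1 at ``t_ref``, continuous at ``t_threshold``.

    Below the threshold the amplitude grows as ``q10_slow**((t - t_ref)/10)``;
    above it the accumulated factor continues with ``q10_steep``.
    """
    t = np.asarray(t_c, dtype=float)
    th, tr = profile.t_threshold, profile.t_ref
    lo = np.minimum(t, th) - tr
    hi = np.maximum(t, th) - th
    out = profile.q10_slow ** (lo / 10.0) * profile.q10_steep ** (hi / 10.0)
    return float(out) if np.isscalar(t_c) else out


@dataclass(frozen=True)
class InactivationParams:
    """Mono-exponential inactivation: time constant (ms) and steady fraction.

    ``tau_ms=None`` disables inactivation (peak and steady state coincide).
    """

    tau_ms: float | None = None
    h_inf: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_ms is not None and self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0 or None")
        if not 0.0 <= self.h_inf <= 1.0:
            raise ValueError("h_inf must lie in [0, 1]")

    def survival(self, t_ms):
        return inactivation_time_course(t_ms, self)


def inactivation_time_course(t_ms, params: InactivationParams):
    """Fraction of non-inactivated channels ``h(t) = h_inf + (1-h_inf) exp(-t/tau)``."""
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("elapsed time must be >= 0")
    if params.tau_ms is None:
        out = np.ones_like(t)
    else:
        out = params.h_inf + (1.0 - params.h_inf) * np.exp(-t / params.tau_ms)
    return float(out) if np.isscalar(t_ms) else out


@dataclass(frozen=True)
class DensityAnchor:
    """One calibration point: measured current density at (protocol, V, T), at the peak."""

    protocol: str  # "step" | "ramp"
    v_mv: float
    temperature_c: float
    density_pa_pf: float


@dataclass(frozen=True)
class PermeationAnchors:
    """Reversal potential and the condition's current-density calibration table."""

    v_rev_mv: float = 0.0
    anchors: tuple[DensityAnchor, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for a in self.anchors:
            if a.protocol not in ("step", "ramp"):
                raise ValueError(f"unknown protocol tag {a.protocol!r}")
            key = (a.protocol, a.v_mv, a.temperature_c)
            if key in seen:
                raise ValueError(f"duplicate anchor {key}")
            seen.add(key)


@dataclass(frozen=True)
class ConditionPreset:
    """Generative parameters for one experimental condition.

    ``thermal_mode`` selects how temperature enters the gated current:

    * ``"anchored"`` — mechanistic: ``V1/2``/``k`` shift with temperature and
      the conductance amplitude is log-interpolated through the density
      anchors (exact at every anchor).
    * ``"q10"`` — direct: voltage dependence frozen at the cold anchors and
      amplitude follows the exact piecewise-Q10 law. Used where downstream
      analysis must see a clean two-phase Arrhenius response.
    """

    name: str
    gating: ThermalGatingProfile
    inactivation: InactivationParams
    permeation: PermeationAnchors
    leak_density_pa_pf: float  # at -80 mV; ohmic and temperature-insensitive
    cm_mean_pf: float
    cm_sd_pf: float
    cell_scale_cv: float
    thermal_mode: Literal["anchored", "q10"] = "anchored"
    notes: str = ""

    def __post_init__(self) -> None:
        if not 2.0 <= self.cm_mean_pf <= 3.5:
            raise ValueError(f"cm_mean_pf {self.cm_mean_pf} outside [2.0, 3.5] pF")
        if self.cm_sd_pf < 0 or self.cell_scale_cv < 0:
            raise ValueError("cm_sd_pf and cell_scale_cv must be >= 0")
        if self.thermal_mode not in ("anchored", "q10"):
            raise ValueError(f"unknown thermal_mode {self.thermal_mode!r}")
        vr = self.permeation.v_rev_mv
        for a in self.permeation.anchors:
            gated = a.density_pa_pf - self.leak_density(a.v_mv)
            if gated * (a.v_mv - vr) <= 0:
                raise ValueError(
                    f"anchor at {a.v_mv} mV: density sign inconsistent with "
                    f"reversal at {vr} mV"
                )

    # ---- leak ---------------------------------------------------------

    def leak_density(self, v_mv):
        """Ohmic leak through the reversal potential, anchored at -80 mV."""
        v = np.asarray(v_mv, dtype=float)
        vr = self.permeation.v_rev_mv
        out = self.leak_density_pa_pf * (v - vr) / (-80.0 - vr)
        return float(out) if np.isscalar(v_mv) else out

    # ---- gating as seen by the generator ------------------------------

    def effective_gating(self, t_c: float) -> BoltzmannGating:
        """Gating used at temperature t: frozen at the cold anchor in 'q10' mode."""
        if self.thermal_mode == "q10":
            return self.gating.gating_at(self.gating.t_ref)
        return self.gating.gating_at(t_c)

    # ---- conductance calibration --------------------------------------

    def _conductance_law(self, protocol: str, side: int):
        """ln-conductance anchors (temps, ln g) for one protocol and voltage side.

        Falls back to the other protocol, then to the mirrored side. Returns
        None when the preset has no anchors at all (pure leak).
        """
        if not self.permeation.anchors:
            return None
        vr = self.permeation.v_rev_mv
        for proto in (protocol, "ramp" if protocol == "step" else "step"):
            for s in (side, -side):
                pts = []
                for a in self.permeation.anchors:
                    if a.protocol != proto:
                        continue
                    if int(np.sign(a.v_mv - vr)) != s:
                        continue
                    gated = a.density_pa_pf - self.leak_density(a.v_mv)
                    po = open_probability(a.v_mv, self.effective_gating(a.temperature_c))
                    if self.thermal_mode == "q10":
                        # refer the anchor back to t_ref through the Q10 law
                        po *= self.gating.conductance_scale(a.temperature_c)
                    g = gated / (po * (a.v_mv - vr))
                    if g <= 0:
                        raise PresetError(
                            f"{self.name}: anchor at {a.v_mv} mV, "
                            f"{a.temperature_c} °C implies non-positive conductance"
                        )
                    pts.append((a.temperature_c, math.log(g)))
                if pts:
                    pts.sort()
                    return np.array(pts, dtype=float)
        return None

    def _conductance_at(self, protocol: str, side: int, t_c: float) -> float:
        law = self._conductance_law(protocol, side)
        if law is None:
            return 0.0
        temps, lng = law[:, 0], law[:, 1]
        if self.thermal_mode == "q10":
            # anchors are referred to t_ref; amplitude follows the Q10 law.
            return math.exp(lng[0]) * self.gating.conductance_scale(t_c)
        if t_c <= temps[0]:
            scale = self.gating.conductance_scale(t_c) / self.gating.conductance_scale(temps[0])
            return math.exp(lng[0]) * scale
        if t_c >= temps[-1]:
            scale = self.gating.conductance_scale(t_c) / self.gating.conductance_scale(temps[-1])
            return math.exp(lng[-1]) * scale
        return math.exp(float(np.interp(t_c, temps, lng)))

    # ---- the composed model -------------------------------------------

    def gated_density(self, v_mv, t_c: float, elapsed_ms: float = 0.0,
                      protocol: str = "ramp"):
        """Gated current density (pA/pF), excluding leak, at the given phase.

        ``elapsed_ms`` is the time since activation onset and drives the
        inactivation factor.
        """
        v = np.asarray(v_mv, dtype=float)
        vr = self.permeation.v_rev_mv
        gating = self.effective_gating(t_c)
        po = open_probability(v, gating)
        h = float(inactivation_time_course(float(elapsed_ms), self.inactivation))
        g_neg = self._conductance_at(protocol, -1, t_c)
        g_pos = self._conductance_at(protocol, +1, t_c)
        g = np.where(v < vr, g_neg, g_pos)
        out = po * (v - vr) * g * h
        return float(out) if np.isscalar(v_mv) else out

    def current_density(self, v_mv, t_c: float, elapsed_ms: float = 0.0,
                        protocol: str = "ramp"):
        """Total current density: gated + leak, inward negative."""
        gated = self.gated_density(v_mv, t_c, elapsed_ms, protocol)
        return gated + self.leak_density(v_mv)


def current_density_model(v_mv, t_c, elapsed_ms, preset: ConditionPreset,
                          measure_phase: str = "peak", protocol: str = "ramp"):
    """Noise-free model current density at an anchor-calibrated condition.

    ``measure_phase="peak"`` evaluates at activation onset (no inactivation);
    ``"steady"`` evaluates the fully inactivated level regardless of
    ``elapsed_ms``.
    """
    if measure_phase == "peak":
        elapsed = 0.0
    elif measure_phase == "steady":
        elapsed = math.inf if preset.inactivation.tau_ms is not None else 0.0
    elif measure_phase == "timed":
        elapsed = float(elapsed_ms)
    else:
        raise ValueError(f"unknown measure_phase {measure_phase!r}")
    return preset.current_density(v_mv, t_c, elapsed, protocol)


# ---------------------------------------------------------------------------
# Serialization: one flat, human-readable TOML document per condition.
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)  # shortest round-trip representation
    if isinstance(v, int):
        return str(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"cannot serialize {type(v)}")


def preset_to_toml(preset: ConditionPreset) -> str:
    g, inact, perm = preset.gating, preset.inactivation, preset.permeation
    lines = [
        f"name = {_fmt(preset.name)}",
        f"thermal_mode = {_fmt(preset.thermal_mode)}",
        f"notes = {_fmt(preset.notes)}",
        "",
        f"v_half_cold = {_fmt(float(g.v_half_cold))}",
        f"v_half_hot = {_fmt(float(g.v_half_hot))}",
        f"k_cold = {_fmt(float(g.k_cold))}",
        f"k_hot = {_fmt(float(g.k_hot))}",
        f"q10_slow = {_fmt(float(g.q10_slow))}",
        f"q10_steep = {_fmt(float(g.q10_steep))}",
        f"t_threshold = {_fmt(float(g.t_threshold))}",
        f"transition_center = {_fmt(float(g.transition_center))}",
        f"transition_width = {_fmt(float(g.transition_width))}",
        f"t_ref = {_fmt(float(g.t_ref))}",
        f"t_hot = {_fmt(float(g.t_hot))}",
        "",
        f"tau_ms = {_fmt(float(inact.tau_ms)) if inact.tau_ms is not None else _fmt('none')}",
        f"h_inf = {_fmt(float(inact.h_inf))}",
        "",
        f"v_rev_mv = {_fmt(float(perm.v_rev_mv))}",
        "density_anchors = [",
    ]
    for a in perm.anchors:
        lines.append(
            f"    [{_fmt(a.protocol)}, {_fmt(float(a.v_mv))}, "
            f"{_fmt(float(a.temperature_c))}, {_fmt(float(a.density_pa_pf))}],"
        )
    lines += [
        "]",
        "",
        f"leak_density_pa_pf = {_fmt(float(preset.leak_density_pa_pf))}",
        f"cm_mean_pf = {_fmt(float(preset.cm_mean_pf))}",
        f"cm_sd_pf = {_fmt(float(preset.cm_sd_pf))}",
        f"cell_scale_cv = {_fmt(float(preset.cell_scale_cv))}",
        "",
    ]
    return "\n".join(lines)


def preset_from_toml(text: str) -> ConditionPreset:
    try:
        d = tomllib.loads(text)
    except tomllib.TOMLDecodeError as e:
        raise PresetError(f"malformed preset document: {e}") from e
    try:
        gating = ThermalGatingProfile(
            v_half_cold=d["v_half_cold"], v_half_hot=d["v_half_hot"],
            k_cold=d["k_cold"], k_hot=d["k_hot"],
            q10_slow=d["q10_slow"], q10_steep=d["q10_steep"],
            t_threshold=d["t_threshold"],
            transition_center=d["transition_center"],
            transition_width=d["transition_width"],
            t_ref=d["t_ref"], t_hot=d["t_hot"],
        )
        tau = d["tau_ms"]
        inact = InactivationParams(
            tau_ms=None if tau == "none" else float(tau), h_inf=d["h_inf"]
        )
        anchors = tuple(
            DensityAnchor(protocol=a[0], v_mv=float(a[1]),
                          temperature_c=float(a[2]), density_pa_pf=float(a[3]))
            for a in d["density_anchors"]
        )
        perm = PermeationAnchors(v_rev_mv=d["v_rev_mv"], anchors=anchors)
        return ConditionPreset(
            name=d["name"], gating=gating, inactivation=inact, permeation=perm,
            leak_density_pa_pf=d["leak_density_pa_pf"],
            cm_mean_pf=d["cm_mean_pf"], cm_sd_pf=d["cm_sd_pf"],
            cell_scale_cv=d["cell_scale_cv"],
            thermal_mode=d["thermal_mode"], notes=d.get("notes", ""),
        )
    except KeyError as e:
        raise PresetError(f"preset document missing key {e}") from e


def available_presets() -> tuple[str, ...]:
    return PRESET_NAMES


def load_preset(name: str) -> ConditionPreset:
    """Load a packaged condition preset by name (see :func:`available_presets`)."""
    if name not in _PRESET_FILES:
        raise PresetError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    text = (resources.files("thermoclamp") / "presets" / _PRESET_FILES[name]).read_text(
        encoding="utf-8"
    )
    preset = preset_from_toml(text)
    if preset.name != name:
        raise PresetError(f"preset file for {name!r} declares name {preset.name!r}")
    return preset


def save_preset(preset: ConditionPreset, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(preset_to_toml(preset), encoding="utf-8")
    return path
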