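"""Conductance-voltage curves from tail currents and Boltzmann fits.

The tail-current amplitude immediately after repolarization to a fixed tail
potential is proportional to the open probability reached at the preceding
step level, so the normalized tail-vs-step-voltage curve is the channel's
activation (G-V) curve. It is fitted with

    g(V) = g_max / (1 + exp((V1/2 − V) / k)),

with the relative maximum ``g_max`` a bounded free parameter: curves far from
saturation at +80 mV (shallow slope factors) would otherwise bias the
midpoint. Initialization is by logit linearization of the interior points,
which on exact Boltzmann data already recovers the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .features import baseline_subtract, extract_amplitude
from .traceio import DatasetManifest, SweepRecord

__all__ = [
    "GVCurve",
    "BoltzmannFit",
    "GVFitError",
    "build_gv",
    "logit_initializer",
    "fit_boltzmann",
    "gv_from_dataset",
    "GMAX_BOUNDS",
]

GMAX_BOUNDS = (0.8, 1.2)


class GVFitError(ValueError):
    pass


@dataclass(frozen=True)
class GVCurve:
    """Relative conductance vs step voltage, normalized to the largest |tail|."""

    v_mv: np.ndarray
    g_rel: np.ndarray
    sem: np.ndarray
    temperature_c: float
    n_cells: int

    def __post_init__(self) -> None:
        if len(self.v_mv) < 4:
            raise ValueError("G-V curve needs >= 4 points")
        if np.any(self.g_rel < 0) or np.any(self.g_rel > 1 + 3 * np.max(self.sem) + 1e-12):
            raise ValueError("g_rel outside [0, 1 + 3·SEM]")


@dataclass(frozen=True)
class BoltzmannFit:
    v_half_mv: float
    slope_k_mv: float
    g_max: float
    rss: float
    n_points: int
    converged: bool
    se_v_half: float
    se_k: float
    monotonic: bool = True
    flag_reason: str = ""


def build_gv(tails_by_level: dict, temperature_c: float = math.nan) -> GVCurve:
    """G-V curve from tail amplitudes keyed by step level.

    Each value is a sequence of per-cell tail amplitudes (pA or pA/pF) at a
    common tail potential. Cells are averaged per voltage first and the mean
    curve is then normalized by its largest magnitude, matching how grouped
    G-V curves with SEM bars are conventionally built.
    """
    if len(tails_by_level) < 4:
        raise GVFitError("need >= 4 step levels")
    levels = np.array(sorted(tails_by_level), dtype=float)
    means, sems, ns = [], [], []
    for v in levels:
        vals = np.asarray(tails_by_level[v], dtype=float)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    means = np.abs(np.array(means))
    sems = np.array(sems)
    gmax = means.max()
    if gmax == 0:
        raise GVFitError("all tail amplitudes are zero")
    return GVCurve(v_mv=levels, g_rel=means / gmax, sem=sems / gmax,
                   temperature_c=float(temperature_c), n_cells=int(min(ns)))


def logit_initializer(v: np.ndarray, g: np.ndarray, g_max: float = 1.0
                      ) -> tuple[float, float]:
    """(v_half, k) from the logit linearization ln(g/(g_max−g)) = (v−v_half)/k.

    Uses interior points only (1–99% of g_max). On exact Boltzmann data with
    the true g_max this is already the exact solution, which makes it both
    the optimizer's starting point and an independent oracle for it.
    """
    frac = np.asarray(g, dtype=float) / g_max
    sel = (frac > 0.01) & (frac < 0.99)
    if sel.sum() < 2:
        raise GVFitError("fewer than 2 interior points for logit initialization")
    yy = np.log(frac[sel] / (1.0 - frac[sel]))
    slope, intercept = np.polyfit(np.asarray(v, dtype=float)[sel], yy, 1)
    if slope <= 0:
        raise GVFitError("non-increasing logit; cannot initialize")
    return float(-intercept / slope), float(1.0 / slope)


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G-V curve.

    ``g_max`` is bounded to [0.8, 1.2]; standard errors come from the fit's
    curvature. Non-convergence and a significantly decreasing trend of g
    with voltage are flagged, not silently fitted.
    """
    v = np.asarray(gv.v_mv, dtype=float)
    g = np.asarray(gv.g_rel, dtype=float)

    # monotonicity screen: overall downward trend beyond noise is flagged
    slope, intercept = np.polyfit(v, g, 1)
    resid = g - (slope * v + intercept)
    n = len(v)
    se_slope = math.sqrt(
        (resid @ resid) / max(n - 2, 1) / float((v - v.mean()) @ (v - v.mean()))
    )
    monotonic = not (slope < 0 and abs(slope) > 2 * se_slope)

    try:
        vh0, k0 = logit_initializer(v, g, g_max=1.0)
    except GVFitError:
        vh0, k0 = float(np.median(v)), 25.0

    def model(vv, vh, k, gmax):
        return gmax / (1.0 + np.exp((vh - vv) / k))

    try:
        popt, pcov = curve_fit(
            model, v, g, p0=[vh0, max(k0, 1.0), 1.0],
            bounds=([-500.0, 0.01, GMAX_BOUNDS[0]], [500.0, 500.0, GMAX_BOUNDS[1]]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt = np.array([vh0, max(k0, 1.0), 1.0])
        pcov = np.full((3, 3), np.nan)
        converged = False
    vh, k, gmax = (float(p) for p in popt)
    r = g - model(v, vh, k, gmax)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    reason = "" if converged else "optimizer did not converge"
    if not monotonic:
        reason = (reason + "; " if reason else "") + "g decreases with voltage beyond noise"
    return BoltzmannFit(
        v_half_mv=vh, slope_k_mv=k, g_max=gmax, rss=float(r @ r),
        n_points=n, converged=converged,
        se_v_half=float(se[0]), se_k=float(se[1]),
        monotonic=monotonic, flag_reason=reason,
    )


def gv_from_dataset(sweeps, manifest: DatasetManifest, temperature_c: float,
                    baseline: str = "holding") -> GVCurve:
    """Tail extraction → G-V curve for all step sweeps near a temperature."""
    chosen = [s for s in sweeps
              if s.protocol == "step" and not s.is_baseline
              and abs(s.temperature_c - temperature_c) < 0.5]
    if not chosen:
        raise GVFitError(f"no step sweeps at {temperature_c} °C")
    tails: dict[float, list[float]] = {}
    for sw in chosen:
        corr = baseline_subtract(sw, baseline)
        amp = extract_amplitude(corr, "tail")
        cm = manifest.cm_for(sw.cell_id)
        tails.setdefault(float(sw.step_level_mv), []).append(amp.value_pa / cm)
    return build_gv(tails, temperature_c=temperature_c)
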