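"""Thermal-threshold and Q10 analysis by segmented Arrhenius regression.

Procedure: currents sampled at a fixed ramp voltage across bath temperatures
are normalized to the value at the lowest temperature, log10-transformed and
plotted against reciprocal absolute temperature. The initial slow phase and
the steep phase are fitted with independent straight lines over every
admissible split of the ordered points; the split minimizing pooled residual
sum of squares wins, and the two lines' intersection, mapped back to °C, is
the thermal threshold T_h. Each segment's slope is converted to a Q10 — the
fold-change in current per 10 °C.

The slope→Q10 conversion uses a 10 °C window centred on the segment's
midpoint temperature: with slope m on the (1/T_K, log10 I/I_min) axes,

    Q10 = 10 ** (−m · 10 / ((T_K − 5)(T_K + 5))),   T_K = midpoint in K,

which is exactly the two-point formula ``Q10 = (I2/I1)^(10/(T2−T1))``
evaluated on the fitted line at the window's endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermalSeries",
    "TwoPhaseFit",
    "ThermalFitError",
    "q10_two_point",
    "arrhenius_transform",
    "fit_two_phase",
    "q10_from_slope",
    "analyze_series",
    "cohort_thermal_summary",
    "KELVIN_OFFSET",
]

KELVIN_OFFSET = 273.15
MIN_SEGMENT_POINTS = 4


class ThermalFitError(ValueError):
    pass


@dataclass(frozen=True)
class ThermalSeries:
    """Current sampled at a fixed ramp voltage across bath temperatures."""

    temperature_c: np.ndarray
    current: np.ndarray
    cell_id: str = ""
    sample_rule: str = ""
    units: str = "pA"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_c, dtype=float)
        if len(t) != len(self.current):
            raise ValueError("temperature and current lengths differ")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TwoPhaseFit:
    """Segmented Arrhenius fit: two free lines, threshold at their intersection."""

    break_index: int  # last point of the slow (low-temperature) segment
    t_threshold_c: float
    slope_slow: float  # d log10(I/Imin) / d (1/T_K)
    slope_steep: float
    q10_slow: float
    q10_steep: float
    rss_slow: float
    rss_steep: float
    rss_total: float
    n_slow: int
    n_steep: int
    flagged: bool = False
    flag_reason: str = ""


def q10_two_point(i1: float, i2: float, t1_c: float, t2_c: float) -> float:
    """Two-point temperature coefficient ``(|I2|/|I1|) ** (10/(T2−T1))``."""
    if i1 == 0 or i2 == 0:
        raise ThermalFitError("zero current in Q10 computation")
    if i1 * i2 < 0:
        raise ThermalFitError("currents change sign between the two points")
    if t1_c == t2_c:
        raise ThermalFitError("equal temperatures")
    return (abs(i2) / abs(i1)) ** (10.0 / (t2_c - t1_c))


def arrhenius_transform(series: ThermalSeries) -> tuple[np.ndarray, np.ndarray]:
    """Map a thermal series to (x = 1/T_K, y = log10(|I| / |I_min|)) points.

    ``I_min`` is the current at the lowest sampled temperature, so the first
    point maps to y = 0; rescaling all currents leaves y unchanged.
    """
    i = np.asarray(series.current, dtype=float)
    t = np.asarray(series.temperature_c, dtype=float)
    if np.any(i == 0):
        raise ThermalFitError("zero current in series")
    if np.any(i * i[0] < 0):
        raise ThermalFitError("current changes sign within series")
    x = 1.0 / (t + KELVIN_OFFSET)
    y = np.log10(np.abs(i) / abs(i[0]))
    return x, y


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + m x; returns (a, m, rss)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    if denom == 0:
        raise ThermalFitError("degenerate x values in segment")
    m = float(dx @ (y - ym)) / denom
    a = ym - m * xm
    r = y - (a + m * x)
    return a, m, float(r @ r)


def q10_from_slope(slope: float, t_mid_c: float) -> float:
    """Q10 from an Arrhenius-line slope, exact over a centred 10 °C window."""
    if not math.isfinite(slope):
        raise ThermalFitError("non-finite slope")
    tk = t_mid_c + KELVIN_OFFSET
    return 10.0 ** (-slope * 10.0 / ((tk - 5.0) * (tk + 5.0)))


def fit_two_phase(temperature_c: np.ndarray, x: np.ndarray, y: np.ndarray,
                  min_pts: int = MIN_SEGMENT_POINTS) -> TwoPhaseFit:
    """Exhaustive breakpoint scan over Arrhenius points ordered by temperature.

    Points must be sorted by increasing temperature. Every split leaving at
    least ``min_pts`` points per side is fitted with two independent OLS
    lines; minimal pooled RSS wins, ties broken toward the breakpoint nearest
    the median temperature. The threshold is the analytic intersection of the
    two lines mapped back to °C; an intersection outside the sampled range is
    flagged (threshold reported at the boundary), parallel lines are an error.
    """
    t = np.asarray(temperature_c, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    if not (len(x) == len(y) == n):
        raise ThermalFitError("mismatched input lengths")
    if n < 2 * min_pts:
        raise ThermalFitError(
            f"need >= {2 * min_pts} points for a two-phase fit, got {n}"
        )
    if np.any(np.diff(t) <= 0):
        raise ThermalFitError("temperatures must be strictly increasing")

    t_median = float(np.median(t))
    best = None  # (rss, |t_break - t_median|, k, fits)
    for k in range(min_pts - 1, n - min_pts):  # k = index of last slow point
        a1, m1, rss1 = _ols_line(x[: k + 1], y[: k + 1])
        a2, m2, rss2 = _ols_line(x[k + 1:], y[k + 1:])
        rss = rss1 + rss2
        t_break = 0.5 * (t[k] + t[k + 1])
        key = (rss, abs(t_break - t_median))
        if best is None or key < best[0]:
            best = (key, k, (a1, m1, rss1), (a2, m2, rss2))
    (rss_total, _), k, (a1, m1, rss1), (a2, m2, rss2) = best

    if math.isclose(m1, m2, rel_tol=1e-12, abs_tol=1e-15):
        raise ThermalFitError("segments are parallel; no threshold defined")
    x_star = (a2 - a1) / (m1 - m2)
    flagged, reason = False, ""
    if x_star <= 0:
        flagged, reason = True, "intersection at non-physical temperature"
        th = float(t[k])
    else:
        th = 1.0 / x_star - KELVIN_OFFSET
        if not (t[0] <= th <= t[-1]):
            flagged = True
            reason = f"intersection {th:.2f} °C outside sampled range"
            th = float(np.clip(th, t[0], t[-1]))

    t_mid_slow = 0.5 * (t[0] + t[k])
    t_mid_steep = 0.5 * (t[k + 1] + t[-1])
    return TwoPhaseFit(
        break_index=k, t_threshold_c=float(th),
        slope_slow=m1, slope_steep=m2,
        q10_slow=q10_from_slope(m1, t_mid_slow),
        q10_steep=q10_from_slope(m2, t_mid_steep),
        rss_slow=rss1, rss_steep=rss2, rss_total=rss_total,
        n_slow=k + 1, n_steep=n - k - 1,
        flagged=flagged, flag_reason=reason,
    )


def analyze_series(series: ThermalSeries, min_pts: int = MIN_SEGMENT_POINTS
                   ) -> TwoPhaseFit:
    """Arrhenius transform followed by the two-phase fit, for one cell."""
    t = np.asarray(series.temperature_c, dtype=float)
    if t[-1] - t[0] < 10.0:
        raise ThermalFitError(
            f"series spans only {t[-1] - t[0]:.1f} °C; >= 10 °C required"
        )
    x, y = arrhenius_transform(series)
    return fit_two_phase(t, x, y, min_pts=min_pts)


def cohort_thermal_summary(fits) -> dict:
    """Per-cell fits → cohort mean ± SEM of Q10_slow, Q10_steep and T_h."""
    fits = list(fits)
    if not fits:
        raise ThermalFitError("no fits to summarize")

    def _ms(vals):
        v = np.asarray(vals, dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return {"mean": float(v.mean()), "sem": sem, "n": len(v)}

    return {
        "q10_slow": _ms([f.q10_slow for f in fits]),
        "q10_steep": _ms([f.q10_steep for f in fits]),
        "t_threshold_c": _ms([f.t_threshold_c for f in fits]),
        "n_flagged": sum(f.flagged for f in fits),
    }


def bootstrap_cohort(fits, n_boot: int = 1000, seed: int = 0) -> dict:
    """Bootstrap over cells: 2.5–97.5 percentile intervals for the summary."""
    fits = list(fits)
    rng = np.random.default_rng(seed)
    th = np.array([f.t_threshold_c for f in fits])
    qs = np.array([f.q10_slow for f in fits])
    qt = np.array([f.q10_steep for f in fits])
    idx = rng.integers(0, len(fits), size=(n_boot, len(fits)))
    out = {}
    for name, v in (("t_threshold_c", th), ("q10_slow", qs), ("q10_steep", qt)):
        means = v[idx].mean(axis=1)
        out[name] = (float(np.percentile(means, 2.5)),
                     float(np.percentile(means, 97.5)))
    return out
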