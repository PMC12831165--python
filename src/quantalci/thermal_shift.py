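"""Melt-curve processing for dye-based thermal shift assays.

A thermal shift (differential scanning fluorimetry) curve reports dye
fluorescence against temperature as a protein unfolds. The processing
pipeline is: rescale the raw fluorescence to [0, 1], smooth with a
quadratic Savitzky-Golay filter (rolling window of 15 temperature points),
and call the melt temperature Tm as the temperature of the maximum first
derivative of the smoothed curve. The derivative search is restricted to
the region up to and including the global fluorescence maximum so that the
post-peak decline of dye signal (aggregation / dye release after full
unfolding) cannot masquerade as an unfolding transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter, find_peaks

__all__ = [
    "MeltCurve",
    "MeltResult",
    "normalize_curve",
    "smooth_savgol",
    "melt_temperature",
    "call_tm_table",
]


@dataclass
class MeltCurve:
    """Fluorescence vs temperature for one well."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    well: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.size != self.fluorescence.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperatures.size >= 2 and not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly ascending")


@dataclass
class MeltResult:
    """Tm call with diagnostics.

    ``tm`` is NaN with ``no_call=True`` when the curve shows no rising
    transition. ``secondary_tms`` lists every local derivative peak above
    the prominence threshold (useful for bi-phasic melts).
    """

    tm: float
    derivative: np.ndarray
    temperatures: np.ndarray
    smoothed: np.ndarray
    no_call: bool = False
    secondary_tms: list = field(default_factory=list)
    window: int = 15
    polyorder: int = 2


def normalize_curve(curve: MeltCurve) -> MeltCurve:
    """Linearly rescale fluorescence so min -> 0 and max -> 1."""
    f = curve.fluorescence
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        raise ValueError("constant fluorescence: curve cannot be normalized")
    return MeltCurve(curve.temperatures, (f - lo) / (hi - lo), curve.well)


def smooth_savgol(curve: MeltCurve, window: int = 15, order: int = 2) -> MeltCurve:
    """Savitzky-Golay smoothing on the same temperature grid.

    The window is forced odd; edges are handled by fitting the edge
    polynomial to the last full window (so an order-``order`` polynomial
    input passes through unchanged everywhere, edges included).
    """
    if window % 2 == 0:
        window += 1
    n = curve.fluorescence.size
    if window > n:
        raise ValueError(f"window ({window}) exceeds curve length ({n})")
    smoothed = savgol_filter(curve.fluorescence, window, order, mode="interp")
    return MeltCurve(curve.temperatures, smoothed, curve.well)


def melt_temperature(
    curve: MeltCurve,
    window: int = 15,
    order: int = 2,
    normalized: bool = False,
    peak_prominence: float = 0.2,
) -> MeltResult:
    """Full pipeline Tm call: normalize, smooth, maximum-derivative.

    Set ``normalized=True`` if the curve is already rescaled/smoothed.
    The first derivative is computed by central differences
    (``numpy.gradient``) on the smoothed curve; its maximum over the
    region up to and including the global fluorescence maximum defines Tm.
    A curve whose fluorescence maximum sits at the first grid point (no
    rising phase) yields a flagged no-call.
    """
    work = curve if normalized else smooth_savgol(normalize_curve(curve), window, order)
    T, F = work.temperatures, work.fluorescence
    if T.size < 3:
        raise ValueError("at least 3 points are required")
    dFdT = np.gradient(F, T)
    i_fmax = int(np.argmax(F))
    if i_fmax == 0 or np.all(dFdT[: i_fmax + 1] <= 0):
        return MeltResult(np.nan, dFdT, T, F, no_call=True,
                          window=window, polyorder=order)
    search = dFdT[: i_fmax + 1]
    i_tm = int(np.argmax(search))
    tm = _refine_peak(T[: i_fmax + 1], search, i_tm, half_width=window // 2)
    peaks, _ = find_peaks(search, prominence=peak_prominence * search.max())
    secondary = [float(T[p]) for p in peaks if p != i_tm]
    return MeltResult(tm, dFdT, T, F, no_call=False,
                      secondary_tms=secondary, window=window, polyorder=order)


def _refine_peak(T: np.ndarray, g: np.ndarray, i: int, half_width: int) -> float:
    """Sub-grid location of the derivative maximum.

    Fits a quadratic by least squares to the derivative over +-half_width
    samples around the discrete argmax and returns its vertex (clamped to
    the fit window); falls back to the grid point for degenerate fits.
    """
    lo, hi = max(0, i - half_width), min(T.size, i + half_width + 1)
    if hi - lo < 3:
        return float(T[i])
    t, y = T[lo:hi], g[lo:hi]
    a, b, _ = np.polyfit(t - t.mean(), y, 2)
    if a >= 0:  # not concave: no interior maximum
        return float(T[i])
    vertex = t.mean() - b / (2.0 * a)
    return float(np.clip(vertex, t[0], t[-1]))


def call_tm_table(df: pd.DataFrame, window: int = 15, order: int = 2) -> pd.DataFrame:
    """Call Tm for every well of a long table (well, temperature_c, fluorescence)."""
    required = {"well", "temperature_c", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"melt-curve table missing columns: {sorted(missing)}")
    rows = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("temperature_c")
        curve = MeltCurve(sub["temperature_c"].to_numpy(),
                          sub["fluorescence"].to_numpy(), well=str(well))
        res = melt_temperature(curve, window=window, order=order)
        rows.append({"well": well, "tm_c": res.tm, "no_call": res.no_call,
                     "n_secondary_peaks": len(res.secondary_tms)})
    return pd.DataFrame(rows)
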