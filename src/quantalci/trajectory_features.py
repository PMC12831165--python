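"""Scalar descriptors of pulse-like signaling time courses.

A *trajectory* here is any nonnegative time course associated with one cell
or one fluorescent spot: the number of NEMO puncta per cell over a long
movie, the summed spot intensity per cell, or the intensity of a single
tracked spot. Nine descriptors summarize the pulse: its integral (AUC),
peak height and timing, maximal rise and decay slopes, half-maximum
crossing times and width, and the time of return to the lower plateau
(adaptation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryDescriptors",
    "compute_descriptors",
    "descriptor_table",
    "aggregate_cell_intensity",
    "filter_early_tracks",
    "DESCRIPTOR_COLUMNS",
]

#: Column order used in every descriptor table written by this package.
DESCRIPTOR_COLUMNS = [
    "auc",
    "max",
    "rate_up",
    "rate_down",
    "t_max",
    "t50_up",
    "t50_down",
    "fwhm",
    "adaptation_time",
]


@dataclass
class Trajectory:
    """A sampled time course with optional identifying metadata.

    Parameters
    ----------
    times : array-like
        Sample times in minutes, strictly ascending (need not be regular).
    values : array-like
        Nonnegative signal values (spot counts or intensities).
    metadata : dict
        Free-form identifiers (cell id, species, dose, ...) passed through
        to descriptor tables.
    """

    times: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.times.size} times vs {self.values.size} values"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly ascending")
        if np.any(self.values < 0):
            raise ValueError("trajectory values must be nonnegative")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TrajectoryDescriptors:
    """The nine scalar features of a trajectory.

    Time-based descriptors (``t_max``, ``t50_up``, ``t50_down``, ``fwhm``,
    ``adaptation_time``) are NaN when undefined, e.g. for an all-zero
    trajectory; ``defined`` records whether they are meaningful.
    """

    auc: float
    max: float
    rate_up: float
    rate_down: float
    t_max: float
    t50_up: float
    t50_down: float
    fwhm: float
    adaptation_time: float
    defined: bool = True

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("defined")
        return d


def _max_window_slope(times: np.ndarray, values: np.ndarray) -> float:
    """Largest |OLS slope| over all windows of 3 consecutive samples.

    Falls back to the 2-point slope when the interval holds fewer than
    3 samples, and to 0 for a single sample.
    """
    n = times.size
    if n < 2:
        return 0.0
    if n == 2:
        return abs((values[1] - values[0]) / (times[1] - times[0]))
    best = 0.0
    for i in range(n - 2):
        t = times[i : i + 3]
        v = values[i : i + 3]
        tc = t - t.mean()
        slope = float(np.dot(tc, v - v.mean()) / np.dot(tc, tc))
        best = max(best, abs(slope))
    return best


def _first_crossing(
    times: np.ndarray, values: np.ndarray, level: float, rising: bool
) -> float:
    """First time the piecewise-linear trajectory crosses `level`.

    For a rising crossing, looks for the first sample >= level and
    interpolates from the previous sample; symmetric for falling.
    Returns NaN when no crossing exists.
    """
    if rising:
        hits = np.nonzero(values >= level)[0]
    else:
        hits = np.nonzero(values <= level)[0]
    if hits.size == 0:
        return math.nan
    j = int(hits[0])
    if j == 0:
        return float(times[0])
    v0, v1 = values[j - 1], values[j]
    if v1 == v0:
        return float(times[j])
    frac = (level - v0) / (v1 - v0)
    return float(times[j - 1] + frac * (times[j] - times[j - 1]))


def _adaptation_time(
    times: np.ndarray,
    values: np.ndarray,
    i_max: int,
    vmax: float,
    baseline_fraction: float,
    tolerance_fraction: float,
    hold_samples: int,
) -> float:
    """First time after the peak when the signal settles onto its lower plateau.

    The plateau level is the mean of the trailing `baseline_fraction` of
    samples; the signal must come within `tolerance_fraction` of the
    peak-to-plateau span and stay there for `hold_samples` consecutive
    samples (or all remaining samples, if fewer are left).
    """
    n = times.size
    n_tail = max(1, math.ceil(baseline_fraction * n))
    baseline = float(values[-n_tail:].mean())
    threshold = baseline + tolerance_fraction * (vmax - baseline)
    post = values[i_max:]
    post_t = times[i_max:]
    m = post.size
    for k in range(m):
        need = min(hold_samples, m - k)
        if np.all(post[k : k + need] <= threshold):
            return float(post_t[k])
    return math.nan


def compute_descriptors(
    traj: Trajectory,
    baseline_fraction: float = 0.10,
    tolerance_fraction: float = 0.05,
    hold_samples: int = 3,
) -> TrajectoryDescriptors:
    """Extract the nine pulse descriptors from a trajectory.

    * ``auc`` — trapezoidal integral of the full trajectory.
    * ``max`` / ``t_max`` — global maximum and its time (earliest on ties).
    * ``rate_up`` — largest |slope| from an OLS line through 3 consecutive
      samples between time zero and ``t_max``.
    * ``rate_down`` — same, between ``t_max`` and the end.
    * ``t50_up`` — first time the signal reaches half of ``max``
      (linear interpolation between samples).
    * ``t50_down`` — first time after the peak it falls back to half-max.
    * ``fwhm`` — ``t50_down - t50_up``.
    * ``adaptation_time`` — first time after the peak the signal enters and
      stays within ``tolerance_fraction`` of the span above its trailing
      plateau (mean of the final ``baseline_fraction`` of samples) for
      ``hold_samples`` consecutive samples.

    An all-zero trajectory yields zero AUC/max/rates and NaN time
    descriptors with ``defined=False``.
    """
    if len(traj) < 3:
        raise ValueError("at least 3 samples are required to compute descriptors")
    t, v = traj.times, traj.values
    auc = float(np.trapezoid(v, t))
    vmax = float(v.max())
    if vmax == 0.0:
        nan = math.nan
        return TrajectoryDescriptors(0.0, 0.0, 0.0, 0.0, nan, nan, nan, nan, nan,
                                     defined=False)
    i_max = int(np.argmax(v))  # argmax returns the earliest maximal index
    t_max = float(t[i_max])

    rate_up = _max_window_slope(t[: i_max + 1], v[: i_max + 1])
    rate_down = _max_window_slope(t[i_max:], v[i_max:])

    half = vmax / 2.0
    t50_up = _first_crossing(t[: i_max + 1], v[: i_max + 1], half, rising=True)
    t50_down = _first_crossing(t[i_max:], v[i_max:], half, rising=False)
    fwhm = t50_down - t50_up

    adaptation = _adaptation_time(
        t, v, i_max, vmax, baseline_fraction, tolerance_fraction, hold_samples
    )
    return TrajectoryDescriptors(
        auc=auc, max=vmax, rate_up=rate_up, rate_down=rate_down,
        t_max=t_max, t50_up=t50_up, t50_down=t50_down, fwhm=fwhm,
        adaptation_time=adaptation,
    )


def descriptor_table(trajectories: Sequence[Trajectory], **kwargs) -> pd.DataFrame:
    """Compute descriptors for many trajectories as one table.

    Metadata keys of each trajectory become passthrough columns.
    """
    rows = []
    for traj in trajectories:
        row = dict(traj.metadata)
        row.update(compute_descriptors(traj, **kwargs).as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    meta_cols = [c for c in df.columns if c not in DESCRIPTOR_COLUMNS]
    return df[meta_cols + [c for c in DESCRIPTOR_COLUMNS if c in df.columns]]


def aggregate_cell_intensity(tracks: Sequence, grid: np.ndarray) -> Trajectory:
    """Sum single-spot intensities into a per-cell trajectory on `grid`.

    Each track must expose ``times`` and ``intensity`` arrays (see
    :class:`quantalci.single_complex_model.SpotTrack`). A track contributes
    its linearly interpolated intensity where the grid overlaps its support
    and zero elsewhere (a spot that has not formed, or whose record ended,
    adds nothing).
    """
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for track in tracks:
        t = np.asarray(track.times, dtype=float)
        v = np.asarray(track.intensity, dtype=float)
        total += np.interp(grid, t, v, left=0.0, right=0.0)
    return Trajectory(times=grid, values=total, metadata={"n_tracks": len(tracks)})


def filter_early_tracks(tracks: Sequence, cutoff: float = 4.0) -> list:
    """Keep tracks that formed within the first `cutoff` minutes (inclusive).

    Mirrors the single-particle-tracking convention of only analysing spots
    that appear early in a movie, so that tracks are comparable and minimally
    photobleached. Each track must expose a ``formation_time`` attribute.
    """
    return [tr for tr in tracks if tr.formation_time <= cutoff]
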