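"""Synthetic inputs with the statistical structure the analysis expects.

The study's raw imaging and plate data are not deposited, so every
downstream stage is exercised on generated stand-ins:

* per-cell spot-count time courses — a pulse that rises to a peak within
  tens of minutes and adapts back to baseline, with dose- and
  affinity-dependent amplitude (Hill in dose, effective EC50 =
  reference_ec50 / relative_affinity), lognormal cell-to-cell amplitude
  jitter and Poisson count noise;
* single-spot intensity tracks — the single-complex model resampled at
  10-second framing, mirroring fast imaging;
* melt curves — a two-state unfolding logistic with linear baselines and
  Gaussian noise (optionally a post-peak decline, as dye-based melts show
  after full unfolding);
* a toy three-chain structure with constructed geometry for the contact
  and terminal-distance utilities.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .single_complex_model import SingleComplexParams, SpotTrack, simulate_single_complexes

__all__ = [
    "SyntheticCohortSpec",
    "MeltCurveSpec",
    "gen_spot_count_timecourses",
    "gen_single_spot_tracks",
    "gen_melt_curve",
    "gen_toy_structure",
    "pulse_shape",
]


@dataclass
class SyntheticCohortSpec:
    """One species' synthetic dose-response cohort.

    ``relative_affinity`` shifts the effective EC50 of the amplitude-dose
    relation: EC50_eff = reference_ec50 / relative_affinity, so weaker
    ligands need proportionally more cytokine for the same response.
    Defaults emulate the reference (human-like) condition: responses peak
    near 15 min, adapt by ~90 min, and reach a few tens of spots per cell
    at saturation over a 120-min movie sampled every 2 min.
    """

    species_label: str = "reference"
    relative_affinity: float = 1.0
    doses: tuple = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)  # ng/mL
    n_cells_per_dose: int = 50
    peak_time_mean: float = 15.0       # min
    adaptation_time_mean: float = 90.0  # min
    max_amplitude: float = 40.0        # spots/cell at saturation
    reference_ec50: float = 1.0        # ng/mL at relative_affinity 1
    noise_cv: float = 0.3
    frame_interval: float = 1.0        # min
    duration: float = 120.0            # min
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if self.relative_affinity <= 0:
            raise ValueError("relative_affinity must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.duration < self.adaptation_time_mean:
            raise ValueError("duration must cover the adaptation time")
        if self.peak_time_mean <= 0 or self.adaptation_time_mean <= self.peak_time_mean:
            raise ValueError("need 0 < peak_time_mean < adaptation_time_mean")

    @property
    def effective_ec50(self) -> float:
        return self.reference_ec50 / self.relative_affinity


def pulse_shape(
    times: np.ndarray,
    peak_time: float,
    adaptation_time: float,
    adapt_level: float = 0.05,
) -> np.ndarray:
    """Unit-peak gamma-like pulse: power-law rise times exponential decay.

    ``shape(t) = (t/tp)^k * exp(k * (1 - t/tp))`` peaks at exactly
    ``tp = peak_time`` with value 1; the shape exponent ``k`` is chosen in
    closed form so the pulse has decayed to ``adapt_level`` of its peak by
    ``adaptation_time``: with ``r = adaptation_time / peak_time``,
    ``k = ln(adapt_level) / ln(r * e^(1 - r))`` (well defined for any
    ``r > 1``).
    """
    r = adaptation_time / peak_time
    if r <= 1:
        raise ValueError("adaptation_time must exceed peak_time")
    k = math.log(adapt_level) / math.log(r * math.exp(1.0 - r))
    times = np.asarray(times, dtype=float)
    u = times / peak_time
    with np.errstate(divide="ignore"):
        shape = np.where(u > 0, np.exp(k * (np.log(np.maximum(u, 1e-300)) + 1.0 - u)), 0.0)
    return shape


def gen_spot_count_timecourses(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Per-cell spot-count trajectories for every dose of one cohort.

    Returns a long table (species, dose, cell_id, time, count). Expected
    peak amplitude follows a Hill function of dose (exponent 1) with
    effective EC50 = reference_ec50 / relative_affinity. With
    ``noise_cv > 0`` each cell's amplitude carries a lognormal factor of
    that coefficient of variation and counts are Poisson around the smooth
    mean; with ``noise_cv = 0`` the deterministic expected-count curve is
    returned (real-valued, exact for round-trip fitting).
    """
    times = np.arange(0.0, spec.duration + 0.5 * spec.frame_interval,
                      spec.frame_interval)
    shape = pulse_shape(times, spec.peak_time_mean, spec.adaptation_time_mean)
    rng = np.random.default_rng(spec.seed)
    ec50_eff = spec.effective_ec50

    frames = []
    for dose in spec.doses:
        amp = spec.max_amplitude * dose / (dose + ec50_eff)
        for cell in range(spec.n_cells_per_dose):
            if spec.noise_cv > 0:
                sigma = math.sqrt(math.log1p(spec.noise_cv**2))
                factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                counts = rng.poisson(amp * factor * shape).astype(float)
            else:
                counts = amp * shape
            frames.append(pd.DataFrame({
                "species": spec.species_label,
                "dose": dose,
                "cell_id": cell,
                "time": times,
                "count": counts,
            }))
    return pd.concat(frames, ignore_index=True)


def gen_single_spot_tracks(
    params: SingleComplexParams, n_tracks: int, seed: int = 0
) -> list[SpotTrack]:
    """Single-spot intensity tracks at 10-second framing.

    Thin wrapper over the single-complex simulator producing SPT-like
    fixtures; ``n_tracks = 0`` returns an empty list.
    """
    if n_tracks < 0:
        raise ValueError("n_tracks must be nonnegative")
    if n_tracks == 0:
        return []
    frame = 1.0 / 6.0  # 10 s
    dt = frame / math.ceil(frame / params.dt)  # integration step tiles the frame
    p = replace(params, n_spots=n_tracks, seed=seed, record_interval=frame, dt=dt)
    return simulate_single_complexes(p)


@dataclass
class MeltCurveSpec:
    """Two-state melt-curve generator settings.

    The noiseless curve is ``f_low + pre_slope*(T - T[0])`` blended into
    ``f_low + span + post_slope*(T - midpoint)`` through a logistic of
    width ``slope_scale`` centred at ``midpoint``; Gaussian noise of SD
    ``noise_sd`` is added on top. Defaults mimic a SYPRO-style plate read:
    25-99 °C in 0.5 °C steps.
    """

    midpoint: float = 60.0       # °C
    slope_scale: float = 0.6     # °C (logistic scale; 10-90% width ~2.6 °C)
    pre_slope: float = 0.0       # a.u./°C
    post_slope: float = 0.0      # a.u./°C
    f_low: float = 0.0           # a.u.
    span: float = 1.0            # a.u.
    grid: tuple = tuple(np.arange(25.0, 99.0 + 0.125, 0.25))
    noise_sd: float = 0.0        # a.u.
    post_peak_decline: float = 0.0  # a.u./°C decline beyond full unfolding
    seed: int = 0
    well: str = "A1"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.size < 3 or not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly ascending with >= 3 points")
        if not (grid[0] <= self.midpoint <= grid[-1]):
            raise ValueError("midpoint must lie within the temperature grid")
        if self.noise_sd < 0 or self.slope_scale <= 0 or self.span <= 0:
            raise ValueError("noise_sd >= 0 and slope_scale, span > 0 required")


def gen_melt_curve(spec: MeltCurveSpec):
    """Generate one synthetic melt curve (returns a MeltCurve)."""
    from .thermal_shift import MeltCurve

    T = np.asarray(spec.grid, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-(T - spec.midpoint) / spec.slope_scale))
    pre = spec.f_low + spec.pre_slope * (T - T[0])
    post = spec.f_low + spec.span + spec.post_slope * (T - spec.midpoint)
    f = pre * (1.0 - sig) + post * sig
    if spec.post_peak_decline > 0:
        onset = spec.midpoint + 3.0 * spec.slope_scale
        f = f - spec.post_peak_decline * np.maximum(T - onset, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=T.size)
    return MeltCurve(T, f, well=spec.well)


_PDB_ATOM = ("ATOM  {serial:5d}  CA  ALA {chain}{resseq:4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")


def gen_toy_structure(inter_chain_gap: float = 4.4,
                      terminal_separation: float = 19.9) -> str:
    """PDB text for a three-chain Cα-only toy complex with known geometry.

    Chain A (a 3-residue "ligand") runs along y; chain B (receptor) runs
    along x with its first residue exactly ``inter_chain_gap`` Å from A's
    middle residue — the only A-B pair that close; chain C's C-terminal
    Cα sits exactly ``terminal_separation`` Å from chain B's C-terminal
    Cα. All other inter-chain atom pairs are farther by construction.
    """
    if inter_chain_gap <= 0 or terminal_separation <= 0:
        raise ValueError("gaps must be positive")
    g, ts = inter_chain_gap, terminal_separation
    spacing = 3.8
    atoms = []
    # chain A along y, middle residue at the origin
    for i in range(3):
        atoms.append(("A", i + 1, (0.0, (i - 1) * spacing, 0.0)))
    # chain B along +x, starting at the gap
    for i in range(3):
        atoms.append(("B", i + 1, (g + i * spacing, 0.0, 0.0)))
    # chain C stacked in z above B's C-terminus; its res 3 is C-terminal
    for i in range(3):
        atoms.append(("C", i + 1, (g + 2 * spacing, 0.0, ts + (2 - i) * spacing)))

    lines = []
    serial = 1
    prev_chain = None
    for chain, resseq, (x, y, z) in atoms:
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        lines.append(_PDB_ATOM.format(serial=serial, chain=chain, resseq=resseq,
                                      x=x, y=y, z=z))
        serial += 1
        prev_chain = chain
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
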