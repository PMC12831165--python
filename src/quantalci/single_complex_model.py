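"""Hybrid deterministic-stochastic model of single NEMO-spot dynamics.

Each fluorescent NEMO spot marks one activated receptor complex. Its
intensity ``I`` is a continuous proxy for the size of the local
polyubiquitin scaffold and the amount of NEMO recruited to it; a feedback
variable ``X`` stands in for basal deubiquitinase (DUB) activity recruited
in proportion to the spot. Per spot the deterministic dynamics are

    dI/dt = P_form * P_bound * K_growth / (K_limit + I) - K_dbasal * X * I
    dX/dt = K_xbasal * I - K_xdbasal * X

``P_form`` switches from 0 to 1 at the spot's formation time (spots form at
regular intervals, approximating one stimulated cell). ``P_bound`` encodes
whether the initiating ligand-receptor contact is currently engaged.

Ligand affinity enters through one of three mechanisms (``variant``):

* ``bound_toggle`` — ``P_bound`` is a two-state telegraph process with
  binding rate ``k_bind`` and unbinding rate ``k_unbind_ref / affinity``,
  so lower affinity means shorter bound dwells (lower occupancy).
* ``growth_scale`` — the contact is permanent (``P_bound = 1``) but the
  growth rate is scaled by a bounded, monotone factor
  ``affinity / (affinity + growth_half_affinity)``.
* ``dub_suppression`` — the contact is permanent and high affinity
  suppresses DUB activity: ``K_dbasal`` is replaced by
  ``500 * K_dbasal / (500 * affinity + 1)``.

Between telegraph switching events the ODEs are integrated with a
fixed-step RK4 scheme; switch times are sampled exactly from exponential
dwell distributions and enter each integration step as the exact fraction
of the step spent bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SingleComplexParams",
    "SpotTrack",
    "VARIANTS",
    "ode_rhs",
    "dub_effective_rate",
    "growth_scale_factor",
    "telegraph_occupancy",
    "steady_state_intensity",
    "simulate_single_complexes",
]

VARIANTS = ("bound_toggle", "growth_scale", "dub_suppression")


@dataclass
class SingleComplexParams:
    """Parameters of the single-complex model.

    Intensity is in arbitrary fluorescence units (a.u.), time in minutes.

    Attributes
    ----------
    kgrowth : a.u. * min^-1
        Maximal scaffold growth flux while formed and bound.
    klimit : a.u.
        Growth saturation scale; growth is sub-saturated while I << klimit.
    kdbasal : a.u.^-1 * min^-1
        Basal DUB-mediated disassembly rate coefficient.
    kxbasal, kxdbasal : min^-1
        Production and decay rates of the DUB feedback variable.
    k_bind : min^-1
        Telegraph re-binding rate (bound_toggle variant).
    k_unbind_ref : min^-1
        Reference unbinding rate at affinity 1; the realized rate is
        ``k_unbind_ref / affinity`` so contact duration scales with affinity.
    affinity : dimensionless
        Relative ligand affinity (1 = human-like reference).
    variant : str
        Affinity-coupling mechanism, one of ``VARIANTS``.
    growth_half_affinity : dimensionless
        Half-saturation constant of the growth_scale coupling factor.
    pbound_mode : {"telegraph", "mean_field"}
        Realize P_bound as a stochastic switch, or as its constant
        equilibrium occupancy (deterministic approximation).
    n_spots, spot_interval, t_end, dt, record_interval, seed
        Spots form at 0, spot_interval, 2*spot_interval, ...; integration
        uses fixed step ``dt``; tracks are recorded every
        ``record_interval`` minutes (default 10 s, mirroring fast imaging).
    """

    kgrowth: float = 50.0
    klimit: float = 100.0
    kdbasal: float = 0.002
    kxbasal: float = 0.1
    kxdbasal: float = 0.1
    k_bind: float = 0.5
    k_unbind_ref: float = 0.05
    affinity: float = 1.0
    variant: Literal["bound_toggle", "growth_scale", "dub_suppression"] = "bound_toggle"
    growth_half_affinity: float = 0.1
    pbound_mode: Literal["telegraph", "mean_field"] = "telegraph"
    n_spots: int = 75
    spot_interval: float = 0.25
    t_end: float = 60.0
    dt: float = 0.01
    record_interval: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kgrowth", "klimit", "kdbasal", "kxbasal", "kxdbasal",
                     "k_bind", "k_unbind_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.affinity <= 0:
            raise ValueError("affinity must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_spots < 1:
            raise ValueError("n_spots must be at least 1")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.dt > 0.5:
            raise ValueError(
                "dt too large for a stable explicit integration of the spot ODEs; "
                "use dt <= 0.5 min (default 0.01)"
            )

    def with_affinity(self, affinity: float) -> "SingleComplexParams":
        return replace(self, affinity=affinity)


@dataclass
class SpotTrack:
    """Recorded time course of one simulated (or measured) spot.

    ``bound`` holds the fraction of each preceding record interval spent in
    the bound state (1.0 throughout for the deterministic variants).
    """

    spot_id: int
    times: np.ndarray
    intensity: np.ndarray
    xbasal: np.ndarray
    formation_time: float
    bound: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.xbasal = np.asarray(self.xbasal, dtype=float)
        if np.any(self.intensity < 0) or np.any(self.xbasal < 0):
            raise ValueError("intensity and xbasal must be nonnegative")


def dub_effective_rate(kdbasal: float, affinity: float) -> float:
    """Affinity-suppressed DUB rate: ``500*kdbasal / (500*affinity + 1)``.

    Strictly decreasing in affinity; approaches ``kdbasal/affinity`` for
    large affinity and ``500*kdbasal`` as affinity -> 0.
    """
    if affinity <= 0:
        raise ValueError("affinity must be positive")
    return 500.0 * kdbasal / (500.0 * affinity + 1.0)


def growth_scale_factor(affinity: float, half: float = 0.1) -> float:
    """Bounded monotone growth coupling ``affinity / (affinity + half)``.

    Equals 1 when ``half = 0`` (no coupling), approaches 1 at high affinity.
    """
    if affinity <= 0:
        raise ValueError("affinity must be positive")
    return affinity / (affinity + half)


def telegraph_occupancy(k_bind: float, k_unbind: float) -> float:
    """Equilibrium bound-state probability ``k_bind / (k_bind + k_unbind)``."""
    if k_bind == 0 and k_unbind == 0:
        return 1.0  # degenerate: never switches; spots start bound
    return k_bind / (k_bind + k_unbind)


def _effective_rates(params: SingleComplexParams) -> tuple[float, float]:
    """(kgrowth_eff, kdbasal_eff) after the variant's affinity substitution."""
    kg, kd = params.kgrowth, params.kdbasal
    if params.variant == "growth_scale":
        kg = kg * growth_scale_factor(params.affinity, params.growth_half_affinity)
    elif params.variant == "dub_suppression":
        kd = dub_effective_rate(kd, params.affinity)
    return kg, kd


def ode_rhs(
    I: float, X: float, pform: float, pbound: float, params: SingleComplexParams
) -> tuple[float, float]:
    """Right-hand side of the per-spot ODE pair.

    ``pbound`` may be fractional (time-averaged occupancy over a step).
    Variant-specific substitutions of the growth and DUB rates are applied.
    """
    if I < 0 or X < 0:
        raise ValueError("state must be nonnegative")
    kg, kd = _effective_rates(params)
    dI = pform * pbound * kg / (params.klimit + I) - kd * X * I
    dX = params.kxbasal * I - params.kxdbasal * X
    return dI, dX


def steady_state_intensity(params: SingleComplexParams) -> float:
    """Positive fixed point of the spot ODEs with P_form * P_bound = 1.

    At steady state X* = (kxbasal/kxdbasal) I*, so I* is the unique
    positive root of ``kgrowth/(klimit + I) = (kdbasal*kxbasal/kxdbasal) I^2``
    (rates after the variant substitution). Solved by bracketed
    root-finding.
    """
    kg, kd = _effective_rates(params)
    if min(kg, kd, params.kxbasal, params.kxdbasal) <= 0:
        raise ValueError(
            "steady_state_intensity requires positive kgrowth, kdbasal, "
            "kxbasal and kxdbasal"
        )
    c = kd * params.kxbasal / params.kxdbasal

    def f(I: float) -> float:
        return kg / (params.klimit + I) - c * I * I

    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the steady state")
    return float(brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-15))


def _telegraph_bound_fractions(
    rng: np.ndarray, k_bind: float, k_unbind: float,
    form_step: int, n_steps: int, dt: float,
) -> np.ndarray:
    """Exact per-step bound fractions of one telegraph path.

    The spot starts bound at its formation time (formation *is* a binding
    event); dwell times are exponential. Returns an array of length
    ``n_steps`` with the fraction of each dt-interval spent bound
    (0 before formation).
    """
    frac = np.zeros(n_steps)
    if form_step >= n_steps:
        return frac
    t = form_step * dt
    t_end = n_steps * dt
    bound = True
    while t < t_end:
        rate = k_unbind if bound else k_bind
        if rate == 0:
            dwell = t_end - t  # absorbing state for the rest of the run
        else:
            dwell = rng.exponential(1.0 / rate)
        seg_end = min(t + dwell, t_end)
        if bound:
            i0 = int(t / dt)
            i1 = min(int(math.ceil(seg_end / dt)), n_steps)
            for i in range(i0, i1):
                lo = max(t, i * dt)
                hi = min(seg_end, (i + 1) * dt)
                if hi > lo:
                    frac[i] += (hi - lo) / dt
        t = seg_end
        bound = not bound
    return np.clip(frac, 0.0, 1.0)


def simulate_single_complexes(params: SingleComplexParams) -> list[SpotTrack]:
    """Simulate all spots of one cell and return their recorded tracks.

    Spots form at regular intervals; each spot's (I, X) pair is integrated
    with fixed-step RK4, gated per step by P_form and by the exact bound
    fraction of its telegraph path (or by the constant occupancy in
    mean-field mode / the deterministic variants).
    """
    n_steps = int(round(params.t_end / params.dt))
    dt = params.dt
    n = params.n_spots
    form_times = np.arange(n) * params.spot_interval
    if form_times[-1] >= params.t_end:
        raise ValueError(
            "spot formation schedule exceeds t_end; reduce spot_interval or n_spots"
        )
    form_steps = np.rint(form_times / dt).astype(int)

    # Per-step gating G[spot, step] = P_form * (bound fraction of the step).
    G = np.zeros((n, n_steps))
    if params.variant == "bound_toggle":
        k_unbind = params.k_unbind_ref / params.affinity
        if params.pbound_mode == "telegraph":
            streams = [np.random.default_rng(s)
                       for s in np.random.SeedSequence(params.seed).spawn(n)]
            for i in range(n):
                G[i] = _telegraph_bound_fractions(
                    streams[i], params.k_bind, k_unbind, form_steps[i], n_steps, dt
                )
        else:
            occ = telegraph_occupancy(params.k_bind, k_unbind)
            for i in range(n):
                G[i, form_steps[i]:] = occ
    else:
        for i in range(n):
            G[i, form_steps[i]:] = 1.0

    kg, kd = _effective_rates(params)
    klimit = params.klimit
    kxb, kxd = params.kxbasal, params.kxdbasal

    I = np.zeros(n)
    X = np.zeros(n)

    record_every = max(1, int(round(params.record_interval / dt)))
    rec_steps = list(range(0, n_steps + 1, record_every))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_times = np.array(rec_steps) * dt
    I_rec = np.zeros((n, len(rec_steps)))
    X_rec = np.zeros((n, len(rec_steps)))
    B_rec = np.zeros((n, len(rec_steps)))
    B_rec[:, 0] = G[:, 0]
    rec_idx = 1

    def rhs(Ii, Xi, g):
        dI = g * kg / (klimit + Ii) - kd * Xi * Ii
        dX = kxb * Ii - kxd * Xi
        return dI, dX

    for step in range(n_steps):
        g = G[:, step]
        k1I, k1X = rhs(I, X, g)
        k2I, k2X = rhs(I + 0.5 * dt * k1I, X + 0.5 * dt * k1X, g)
        k3I, k3X = rhs(I + 0.5 * dt * k2I, X + 0.5 * dt * k2X, g)
        k4I, k4X = rhs(I + dt * k3I, X + dt * k3X, g)
        I = I + dt / 6.0 * (k1I + 2 * k2I + 2 * k3I + k4I)
        X = X + dt / 6.0 * (k1X + 2 * k2X + 2 * k3X + k4X)
        # RK4 can overshoot marginally below zero near the I = 0 boundary
        np.maximum(I, 0.0, out=I)
        np.maximum(X, 0.0, out=X)
        if rec_idx < len(rec_steps) and step + 1 == rec_steps[rec_idx]:
            I_rec[:, rec_idx] = I
            X_rec[:, rec_idx] = X
            lo = rec_steps[rec_idx - 1]
            B_rec[:, rec_idx] = G[:, lo: step + 1].mean(axis=1)
            rec_idx += 1

    return [
        SpotTrack(
            spot_id=i,
            times=rec_times.copy(),
            intensity=I_rec[i],
            xbasal=X_rec[i],
            formation_time=float(form_times[i]),
            bound=B_rec[i],
        )
        for i in range(n)
    ]
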