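# quantalci

Models and analysis of quantized cytokine-receptor signaling.

IL-1β orthologs from different species bind the human IL-1 receptor with
affinities spanning several orders of magnitude. That affinity sets how
*sensitive* a cell is — the EC50 of its dose-response — but individual
activated receptor complexes recruit NEMO (the IKK regulatory subunit) in
discrete, affinity-independent packets. `quantalci` packages the
computational machinery behind that picture for systems biologists who
want to simulate, quantify and statistically compare receptor-proximal
signaling dynamics:

* **`assembly_model`** — exact Gillespie (direct-method) simulation of the
  three-step reversible assembly cascade
  `L+R1 ⇌ LR1`, `LR1+R3 ⇌ LR1R3`, `LR1R3+MyD88 ⇌ C`, `C → lost`, where
  relative affinity *Aff* scales `k1_on·Aff` and `k1_off/Aff` only.
* **`single_complex_model`** — hybrid deterministic-stochastic dynamics of
  single NEMO spots, `dI/dt = P_form·P_bound·K_growth/(K_limit+I) −
  K_dbasal·X·I`, `dX/dt = K_xbasal·I − K_xdbasal·X`, with three
  affinity-coupling variants (binding-state toggle, growth scaling, DUB
  suppression `K_dbasal′ = 500·K_dbasal/(500·affinity+1)`).
* **`trajectory_features`** — the nine pulse descriptors (AUC, Max,
  Rate_up, Rate_down, t_max, t50_up, t50_down, FWHM, adaptation time).
* **`dose_response`** — Hill (`y = y_max/(1+(K_A/x)^n)`) and logistic
  (`y = y_max/(1+e^{−K_A(x−x0)})`, x = log10 dose) fits with EC50
  extraction, and Fano-factor (variance/mean) noise analysis.
* **`thermal_shift`** — melt-curve normalization, quadratic
  Savitzky-Golay smoothing (window 15), maximum-derivative Tm calling.
* **`resampling_stats`** — bootstrap of small-sample descriptor means
  (100,000 × size 5) and left-tailed Welch t-tests.
* **`structure_contacts`** — PDB parsing, 4.5 Å residue-contact
  annotation, C-terminal Cα–Cα distances.
* **`synthetic_data`** — seeded generators for spot-count cohorts,
  single-spot tracks, melt curves and a toy structure, so the whole
  pipeline runs without any external data.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Two log decades of affinity, three mechanisms, one question: how much
NEMO does each complex recruit?

```python
import numpy as np
from quantalci.single_complex_model import (
    SingleComplexParams, VARIANTS, simulate_single_complexes)
from quantalci.trajectory_features import Trajectory, compute_descriptors

def mean_auc(variant, affinity, seed):
    params = SingleComplexParams(variant=variant, affinity=affinity,
                                 n_spots=200, seed=seed)
    tracks = simulate_single_complexes(params)
    return np.mean([compute_descriptors(Trajectory(t.times, t.intensity)).auc
                    for t in tracks])

for variant in VARIANTS:
    high, low = mean_auc(variant, 1.0, 101), mean_auc(variant, 0.01, 202)
    print(f"{variant:16s} AUC {high:6.1f} -> {low:5.2f}  "
          f"({high / low:.1f}-fold reduction)")
```

```
bound_toggle     AUC  266.5 -> 33.52  (8.0-fold reduction)
growth_scale     AUC  262.5 -> 31.88  (8.2-fold reduction)
dub_suppression  AUC  283.8 -> 65.50  (4.3-fold reduction)
```

Dropping relative affinity from 1.0 (human-like) to 0.01 (feline-like)
cuts the mean per-complex NEMO AUC 4–8-fold under every coupling
mechanism — the model's prediction that contact duration should throttle
per-complex output, which live-cell single-particle tracking contradicts
(measured per-complex descriptors stay flat across ligands, the signature
of quantized signaling).

The same scaling shows up upstream in the bulk dose-response:

```python
from quantalci.assembly_model import AssemblyParams, scan_dose_affinity
from quantalci.dose_response import fit_logistic

table = scan_dose_affinity(AssemblyParams(seed=7),
                           doses=list(np.logspace(-4, 2, 13)),
                           affs=[1.0, 0.01], n_reps=5)
for aff, sub in table.groupby("aff"):
    means = sub.groupby("dose")["auc"].mean()
    fit = fit_logistic(np.log10(means.index), means.to_numpy())
    print(f"aff {aff:5.2f}: EC50 = {10 ** fit.x0:.3g} ng/mL")
```

```
aff  0.01: EC50 = 0.763 ng/mL
aff  1.00: EC50 = 0.00698 ng/mL
```

A 100-fold affinity drop shifts the EC50 ~100-fold (Δlog10 ≈ 2.0):
sensitivity follows affinity even though per-complex output would not.

An end-to-end synthetic pipeline (cohort generation → descriptors → fits,
Fano, bootstrap comparisons, Tm calls, structure measurements) is available
as `quantalci run --recipe full`, writing CSVs and a checksummed manifest.

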