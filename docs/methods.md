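# Methods

`quantalci` models and analyses how the affinity of a cytokine ligand
(IL-1β and its cross-species orthologs) for its receptor shapes signaling
through receptor-proximal, complex-I-like (CI-like) assemblies, read out
as fluorescent NEMO puncta. The package has two simulation cores — a bulk
stochastic assembly model and a single-complex hybrid model — surrounded
by the quantification machinery used to interpret them: trajectory
descriptors, sigmoid dose-response fits, Fano-factor noise analysis,
melt-curve Tm calling, bootstrap statistics and small structural
utilities. Because the original imaging and plate data are not deposited,
a synthetic-data module generates inputs with the statistical structure
the analysis expects; every pipeline stage runs end-to-end on those.

## Bulk assembly model (`assembly_model`)

CI-like complexes assemble through a three-step reversible mass-action
cascade with a terminal loss step,

    L + R1    ⇌ LR1        k1_on·Aff · [L],  k1_off/Aff
    LR1 + R3  ⇌ LR1R3      k2_on,            k2_off
    LR1R3 + M ⇌ C          k3_on,            k3_off
    C         → lost       k_loss

simulated exactly with Gillespie's direct method. The ligand is a constant
extracellular bath (concentration in ng/mL, never depleted); the relative
affinity `Aff` scales only the primary on-rate up and off-rate down, so it
acts as a net affinity for forming a signaling-competent complex. Loss is
absorbing: the receptor, accessory receptor and adaptor in a lost complex
leave the signaling pool, which is what makes N(t) = C(t) adaptive.

Rate-constant magnitudes are packaged defaults calibrated once to the
stated phenomenology rather than measured values: at `Aff = 1` and
saturating dose, N(t) peaks at several hundred complexes within 30 min
(surface-receptor quantification puts the maximal complex count at a few
hundred per cell) and returns near baseline within 60–120 min. The
defaults also place the cascade in the *capture-limited* regime
(`k2_on·r3_total ≫ k1_off/Aff` down to `Aff = 0.01`): once LR1 forms it is
almost always captured by step 2 before the ligand can dissociate, so the
dose scale of the response is set by the binding flux `k1_on·Aff·[L]` and
the EC50 shifts as 1/Aff — one log decade of EC50 per decade of affinity.
Outside that regime (very fast primary off-rates) the effective
dissociation constant scales as 1/Aff², and the EC50–affinity slope
steepens accordingly; the packaged defaults deliberately sit in the
capture-limited regime that reproduces the observed EC50 shifts.

Replicated dose × affinity scans derive one independent RNG stream per
(dose, affinity, replicate) cell from the master seed, attach the nine
trajectory descriptors of N(t) to each replicate, and return a long table.

## Single-complex model (`single_complex_model`)

Each NEMO spot *i* carries two ODEs — an intensity `I_i` (a continuous
proxy for polyubiquitin scaffold size and NEMO recruitment) and a basal
deubiquitinase feedback `X_i` recruited in proportion to the spot:

    dI/dt = P_form · P_bound · K_growth/(K_limit + I) − K_dbasal · X · I
    dX/dt = K_xbasal · I − K_xdbasal · X

`P_form` switches 0→1 at the spot's formation time; 75 spots form at
regular intervals by default, approximating one stimulated cell. Affinity
couples in through one of three mechanisms:

* **bound_toggle** — `P_bound` is a two-state telegraph process (binding
  rate `k_bind`, unbinding rate `k_unbind_ref/affinity`), so contact
  duration scales with affinity. Dwell times are sampled exactly from
  exponential distributions; each fixed RK4 step of the integrator is
  gated by the exact fraction of that step spent bound, so switch times
  are not quantized to the grid. A `mean_field` option replaces the
  switch with its constant equilibrium occupancy
  `k_bind/(k_bind + k_unbind)`.
* **growth_scale** — permanent contact, growth scaled by the bounded
  monotone factor `affinity/(affinity + K_half)` (default `K_half = 0.1`).
* **dub_suppression** — permanent contact; high affinity suppresses DUB
  activity via `K_dbasal′ = 500·K_dbasal/(500·affinity + 1)` (the factor
  500 is an arbitrary multiplier amplifying the affinity effect).

Parameter defaults are again packaged calibrations, not measurements:
`K_growth = 50`, `K_limit = 100` keep growth sub-saturated over the
simulated hour so production tracks occupancy; `K_xbasal = K_xdbasal =
0.1 min⁻¹` give the feedback a ~10-min response time; `k_bind = 0.5`,
`k_unbind_ref = 0.05 min⁻¹` put telegraph occupancy at ≈ 0.91 for
affinity 1 and ≈ 0.09 for affinity 0.01. Under these defaults a
two-log-decade (feline-like) affinity reduction cuts mean per-spot AUC
4–8-fold in all three variants, and steeper reductions follow at
bovine-like affinities. Spots are never removed — the framework does not
attempt the fully adaptive decay of real spots — so tracks run to `t_end`
(60 min, mirroring 1-h fast imaging at 10-s frames).

The fixed point of the ODE pair with `P_form·P_bound = 1` satisfies
`K_growth/(K_limit + I*) = (K_dbasal·K_xbasal/K_xdbasal)·I*²`;
`steady_state_intensity` solves it by bracketed root-finding and the test
suite checks the integrator lands on it to 10⁻⁴ relative at `dt = 0.01`.
RK4 can undershoot marginally below zero near `I = 0`; states are clamped
nonnegative after each step.

## Trajectory descriptors (`trajectory_features`)

Nine scalars summarize any nonnegative pulse-like time course: AUC
(trapezoid), Max and t_max (earliest global maximum), Rate_up / Rate_down
(largest |OLS slope| over three consecutive samples before / after the
peak, overlapping windows, with a two-point fallback when fewer than three
samples are available), t50_up / t50_down (first half-max crossings,
linearly interpolated between samples), FWHM = t50_down − t50_up, and
adaptation time. The lower plateau needed by the adaptation time is not
fully specified by its verbal definition, so the package defines it as the
mean of the trailing 10 % of samples; the adaptation time is the first
post-peak time the signal enters and stays within 5 % of the
peak-to-plateau span for 3 consecutive samples (all thresholds
configurable; when fewer than 3 samples remain, the remaining samples must
all qualify). All-zero trajectories return zero AUC/Max/rates with time
descriptors flagged undefined rather than fabricated.

Per-cell summed-intensity trajectories are built by linear interpolation
of each track onto a common grid (zero outside a track's support), which
makes AUC exactly additive across tracks. The early-track filter keeps
tracks formed within the first 4 minutes (inclusive boundary), the
convention used to limit photobleaching bias in single-particle tracking.

## Dose-response and noise (`dose_response`)

Mean descriptor values per dose are fitted with two sigmoid forms: the
Hill equation `y = y_max/(1 + (K_A/x)^n)` on linear dose (EC50 = K_A; the
exponent can be pinned to 1), and the logistic
`y = y_max/(1 + e^{−K_A(x − x0)})` on log10 dose (EC50 = 10^x0), the form
used for stochastic-simulation summaries. Fitting uses bounded
least-squares (`scipy.optimize.curve_fit`, all parameters positive) with
data-driven starts and a small multi-start grid; non-convergence returns a
flagged result with a message, never a silent failure. R² is computed on
the fitted mean responses. The Fano factor is the sample variance (ddof=1,
a documented convention) over the mean per (species, dose) group, with
groups excluded when the mean is zero or undefined.

## Thermal shift (`thermal_shift`)

Melt curves are normalized to [0, 1], smoothed with a quadratic
Savitzky-Golay filter over 15 temperature points, and Tm is called as the
temperature of the maximum first derivative (central differences on the
smoothed curve). Two numerical choices matter. First, the derivative
search is restricted to the region up to and including the global
fluorescence maximum, so the post-peak dye-release decline of SYPRO-style
curves cannot masquerade as a transition; for bi-phasic melts all local
derivative peaks above a prominence threshold are reported alongside the
global call. Second, the discrete argmax is refined by a least-squares
parabola over the surrounding window, giving sub-grid resolution — on a
0.25 °C grid with noise at 3 % of span this keeps the recovered midpoint
within 0.2 °C of the generator's across 40–90 °C. Filter edges use
polynomial interpolation (`mode="interp"`), which preserves quadratic
inputs exactly through the boundary.

## Resampling statistics (`resampling_stats`)

Weak ligands yield few trackable spots, so descriptor sets are stabilized
by bootstrapping: 100,000 with-replacement samples of size 5 (the
defaults), reported as the distribution of sample means. Group
comparisons use left-tailed t-tests (H1: first group's mean is lower, the
direction a weaker ligand would move per-complex descriptors), Welch by
default since group sizes are very unequal; a Student option exists. Both
pathways — testing raw descriptor sets and bootstrap distributions — are
exposed; the package tests on raw descriptors and uses the bootstrap for
stabilization/visualization. Two identical zero-variance samples return
p = 0.5 by convention, flagged degenerate. No multiple-testing correction
is applied by default (p-values are reported raw); a Benjamini–Hochberg
step can be added downstream via statsmodels if desired.

## Structure utilities (`structure_contacts`)

PDB parsing goes through Biopython (first model, one altloc per atom,
HETATM excluded by default). A ligand residue contacts a receptor chain
when any of its atoms lies within 4.5 Å (inclusive) of any atom of that
chain — all atoms present in the file, hydrogens included; distances use a
k-d tree and the test suite checks exact agreement with an O(n²)
brute-force oracle plus invariance under rigid-body motion. The
C-terminal Cα–Cα distance between two receptor chains (a proxy for the
separation of their cytoplasmic TIR-domain attachment points, ≈ 19.9 Å in
the IL-1β/IL-1R1/IL-1RAcP crystal complex) takes the highest-numbered
residue with a Cα per chain and reports those residue numbers alongside
the distance, since crystal structures truncate true termini. Chain
identity (which chain is which receptor) is an input, not hard-coded.

## Synthetic data (`synthetic_data`)

*Spot-count cohorts.* The mean response is a unit-peak gamma-like pulse
`(t/t_p)^k e^{k(1−t/t_p)}` whose exponent k is set in closed form so the
pulse decays to 5 % of its peak by the adaptation time; defaults peak at
15 min and adapt by 90 min over a 120-min movie at 1-min frames, matching
the observation that puncta peak within 30 min and re-baseline within
60–120 min. Peak amplitude follows a Hill function of dose (exponent 1)
with effective EC50 = `reference_ec50 / relative_affinity` and saturation
at 40 spots/cell. Cell-to-cell variability is a lognormal amplitude factor
with configurable CV (default 0.3) on top of Poisson count noise; with
`noise_cv = 0` the generator returns the deterministic expected-count
curve (real-valued), so round-trip fits are exact. The generator emulates
pulse timing, dose dependence and count noise — it does not emulate
detection/tracking errors, photobleaching, or receptor-level mechanism, so
passing tests validate the analysis chain, not any biological claim about
real cells.

*Melt curves.* A two-state logistic between linear pre/post baselines on a
25–99 °C grid at 0.25 °C (the plate protocol ramps 0.05 °C/s with
continuous reads), logistic scale 0.6 °C (a sharp, cooperative unfolding
transition), plus i.i.d. Gaussian noise and an optional post-peak decline
emulating dye release.

*Toy structure.* A three-chain Cα-only poly-alanine complex whose minimal
inter-chain distance and C-terminal separation are exact constructor
inputs, giving the structure utilities analytically known answers.

## Pipeline and reproducibility (`cli_io`, `cli`)

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage name (via `numpy.random.SeedSequence`), so a
full recipe re-run reproduces every output checksum; the run manifest
records config, per-stage seeds and timings, and SHA-256 of every output.
Tables are schema-validated CSV (UTF-8, comma, header, '.' decimal; times
in minutes unless suffixed `_s`); extra metadata columns pass through
untouched. The `quantalci` CLI exposes each stage and the recipes
(`dose_response`, `single_complex`, `full`) as thin wrappers over the
library.

## Problem sizes

The packaged analyses run at desk scale by choice: 200 spots per condition
for single-complex comparisons, 500 replicates for SSA equilibrium checks,
5 replicates × 13 doses for EC50 scans, 10⁵ bootstrap iterations, and
1,000 Monte-Carlo repetitions for test calibration.

## Known limitations

* All rate magnitudes in both simulation cores are calibrated defaults,
  not fitted to data; conclusions from them are qualitative (orderings,
  fold-changes, scaling regimes), not quantitative predictions.
* The assembly model omits the IL-1R2 decoy receptor, spatial diffusion
  and downstream IKK/NF-κB dynamics; receptors lost with a mature complex
  never recycle.
* Single-spot tracks do not adapt (no spot removal), and the telegraph
  realization of the binding state is one concrete choice among processes
  consistent with "occupancy decreases with affinity".
* The Tm caller assumes a single dominant rising transition; strongly
  bi-phasic curves are reported with secondary peaks but still receive a
  single primary Tm.
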