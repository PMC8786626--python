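# Methods

## Model

The package implements a deterministic kinetic model of the core
insulin–mTOR–AMPK signaling network: insulin receptor (IR), insulin
receptor substrate (IRS), AKT, the two mTOR complexes (mTORC1, mTORC2),
their endogenous inhibitor DEPTOR, the energy sensors AMPK and SIRT1, and
the autophagy-initiating kinase ULK1.  Each protein is a conserved pool
distributed over an inactive form, an active (phosphorylated) form and,
for the mTOR complexes, a DEPTOR-bound form; 20 species, 32 reactions,
43 kinetic constants and 9 pool totals.

Kinetics are Michaelis–Menten for activation steps (saturable in the
substrate pool, driven either by a velocity constant or by an upstream
active species) and mass action for deactivations, with three exceptions:

* mTORC2 dephosphorylation is saturable (velocity `V_pmTORC2`, Michaelis
  constant `Km_pmTORC2`).  Paired with the saturable phosphorylation this
  makes the mTORC2 stage a zero-order (Goldbeter–Koshland) switch, the
  main source of ultrasensitivity in the network.
* The AMPK→mTORC2 drive saturates in its driver:
  `K_mTORC2_by_pAMPK · pAMPK/(Km_mTORC2_by_pAMPK + pAMPK)`.  A linear
  drive cannot reconcile two observations the model is asked to
  reproduce — a ~24-fold change of active AMPK moving phosphorylated
  mTORC2 only ~4-fold (abundance scans), while a ~60% drop of active AMPK
  collapses phosphorylated mTORC2 by ~70% (SIRT1 inhibition at high
  nutrient).  Saturation in the driver reproduces both: the route is
  insensitive far above its half-saturation point and steeply sensitive
  near it.
* DEPTOR binds the phosphorylated complexes by second-order formation and
  first-order dissociation (sequestration, an additional nonlinearity).

AMPK activation has the composite velocity
`K_AMPK + K_AMPK_by_SIRT1 · SIRT1_active` (basal plus SIRT1-dependent
routes sharing `Km_AMPK`), so SIRT1 availability scales the dominant part
of AMPK input.  Leucine-type amino-acid input is folded into the basal
activation constants rather than modeled as a separate species; TSC2,
LKB1, PI3K, GLUT4 and NAD+ are not represented explicitly.

Units are nM and seconds internally; all interfaces (horizons, windows,
periods) speak hours, with a fixed factor of 3600 s/h.

## Oscillation mechanism and regime structure

The energetic-stress phenotype is a limit cycle with a ~24 h period.  Its
backbone is the negative four-stage loop

    pAMPK → pmTORC2 → pAKT → pmTORC1 ⊣ pAMPK ,

closed through the AMPK→mTORC2 edge.  An elasticity analysis of the
kinetic forms shows why this loop, and only this loop, can oscillate
here: a Michaelis–Menten activation stage with *linear* deactivation has
normalized gain strictly below 1 at any operating point, so a cycle of
such stages can never reach the Hopf threshold (≈4 for four equal lags).
The mTORC2 stage is the exception — with saturable deactivation its gain
is 1/(1−r), where r is the ratio of phosphorylation to maximal
dephosphorylation flux — and the loop crosses the Hopf point when the
mTORC2 stage operates near flux balance (r → 1).

Nutrient input (V_IR) sets the regime: the IRS routes into AKT and mTORC2
add a V_IR-dependent constant drive that moves the mTORC2 stage away from
its sensitive point.  At the baseline calibration the model is a
sustained oscillator at V_IR = 0.002687 nM/s (period ~23.1 h), a damped
oscillator at 0.005, and a steady state at 0.01 and above — the Hopf
boundary sits between 0.00269 and 0.005.

## Baseline calibration

No public parameter table accompanies the network, so the baseline
`ParameterSet` shipped with the package was calibrated by the package
authors in two stages:

1. **Linear-stability targeting.**  The leading complex eigenvalue of the
   reduced Jacobian (active coordinates only, conservation eliminated)
   was driven by bounded derivative-free optimization to: positive real
   part with angular frequency ≈ 2π/24 h at V_IR = 0.002687; small
   negative real part at 0.005; clearly negative at 0.1.
2. **Phenotype fitting.**  With the regime structure constrained, the
   headline intervention read-outs (AMPK-abundance fold changes of
   pmTORC2 and of pmTORC1+pmTORC2 at low/high nutrient; percent changes
   of pAMPK, pmTORC1, pmTORC2 under 10% SIRT1 bioavailability) were fit
   by Powell search in log-parameter space, keeping every constant inside
   the physiological sampling box.

All baseline constants lie inside the global-sensitivity box (below).
Pool totals are order-hundreds nM, chosen so that the AMPK-abundance
scans (20–480 nM) bracket the baseline AMPK pool and the DEPTOR scans
(0–1000 nM) bracket the baseline DEPTOR pool.

## Simulation and classification

* Stiff solver (LSODA, variable order) with rtol 1e-8 / atol 1e-10 by
  default; binding constants may span several orders of magnitude across
  the sampling box, so non-stiff fixed settings are not safe.
* Output grid 0.5 h (48 samples per 24 h period); horizons default to
  1000 h with a 200 h trailing window for envelopes.
* Classification: *sustained* if some tracked output keeps trailing
  relative amplitude > 1e-3 and the last-half amplitude is ≥ 0.95× the
  preceding half; *damped* if above threshold but decaying; *steady*
  otherwise.  The thresholds are arguments of `solve`.
* Non-negativity is not enforced during integration (the exact flow
  preserves it since all fluxes vanish at zero concentration); instead a
  post-hoc check rejects trajectories dipping below −1e-6·max(state), and
  a conservation check rejects pool drift above 1e-5 relative — both
  indicate tolerance misconfiguration rather than model behavior.
* Steady states: long relaxation, then damped-Newton refinement in the
  11 reduced coordinates to ‖rhs‖∞ ≤ 1e-8·‖state‖∞.  Oscillatory regimes
  return the trailing-window time average, flagged `from_oscillation`.
* Period: mean peak-to-peak spacing over the trailing window of the most
  strongly oscillating tracked output, with the spacing SD as a quality
  metric; at least 3 peaks are required.

## Calibration machinery

Three simultaneous criteria, mirrored from the study design the model
serves: (i) stress-regime time courses of pmTORC1/pAMPK/pULK1
(peak-normalized, weighted least squares); (ii) the steady
phosphorylated-to-unphosphorylated mTORC1 ratio under *imposed*
fractional AMPK activation 0.1–1.0 (the AMPK pool's ODEs are removed and
pAMPK pinned — an imposed, not emergent, activation); (iii) steady
pAMPK/pAKT levels under an AICAR-like activator, modeled as a
multiplicative increase of the basal (SIRT1-independent) activation
velocity `K_AMPK` — AICAR's ZMP activates AMPK allosterically, so it
scales the direct route only, which also makes the basal/SIRT1 split
identifiable from activator data.  `fit` alternates stage (a), bounded
quasi-Newton minimization of loss (i) over a configurable free set
(default: five oscillator-core constants), with stage (b), the same
minimizer for losses (ii)+(iii) over {K_AMPK, K_AMPK_by_SIRT1}; a
criterion is "satisfied" at ≤5% of the weighted variance of its target.
Optimization is in log10 space, deterministic, and bounded by the
physiological box.

## Sensitivity analysis

* Local: one forward difference per parameter at Δp = 0.5% of p0,
  reported as the dimensionless normalized derivative.
* Global: Latin hypercube over the kind-derived box (Vmax 0.001–10 nM/s;
  catalytic 1e-6–1 s⁻¹; formation/dissociation 1e-6–10; Km 1–1000 nM),
  log-uniform within each range since ranges span up to seven decades.
  Pool totals are not sampled.  Outputs are steady states (trailing-window
  time averages for oscillatory draws, flagged); failed draws become NaN
  rows and are dropped, with counts logged.
* PRCC is computed as the standard partial rank correlation — Pearson
  correlation of rank residuals after regressing out all other
  parameters' ranks — which is what the acronym denotes; a plain
  covariance quotient of raw draws would not be partial or rank-based.
  Bootstrap confidence intervals (200 resamples by default) accompany
  every entry so reduced-N runs are honestly uncertain.
* Desk-scale default N = 5000; production N is a parameter.

## Synthetic data

The generators emulate the *structure* of the calibration data: noisy
samples of the stress oscillation (period ≈ 24 h, unitless, peak = 1),
a monotone-decreasing imposed-AMPK dose–response of the pmTORC1/mTORC1
ratio, and activator-response levels of pAMPK/pAKT.  Noise is additive
Gaussian with SD proportional to the signal range (digitized experimental
points carry no stated error structure, so a range-proportional model is
the neutral choice); seeds make every dataset bit-reproducible.  They do
not emulate instrument-specific error, unequal sampling, or biological
replicates — passing recovery tests therefore demonstrates identifiability
under idealized noise, not robustness to real experimental artifacts.

## Virtual experiments

Percent change is 100·(treated−control)/control and fold change is
treated/control, always computed on trailing-window means when either
condition is oscillatory; peak-normalization in time-course presentations
is cosmetic and never enters derived quantities.  Scenario results store
the full per-condition outputs so every derived number can be recomputed
from the stored conditions (audit property), plus the complete effective
parameter set.  "AMPK abundance" in scans means the conserved AMPK pool
total; the high-nutrient abundance scan uses V_IR = 0.02 (an alternate
0.2 flag exists where sources disagree).

## Problem sizes

Defaults are desk-scale so a full analysis runs on one CPU in minutes:
2D scans default to tens-per-axis meshes (the methodology supports
1000×1000, which is embarrassingly parallel); global SA defaults to
N = 5000 with N ≈ 1000 used in the bundled reproduction script;
acceptance-grade conservation checks use 100 LHS draws over 1000 h.

## Known limitations

* The baseline is calibrated to reproduce regime structure and headline
  intervention read-outs, not any specific experimental dataset; absolute
  concentrations are arbitrary up to the joint scaling symmetry of
  totals, Michaelis constants and velocities.
* Quantitative agreement across *all* published intervention percentages
  is not achievable simultaneously in this kinetic structure (see the
  driver-saturation discussion); the shipped baseline is a compromise
  optimized in that order: regime structure, period, low-nutrient AMPK
  scan, SIRT1-inhibition pattern.
* No stochastic simulation, no delay terms, no cell-population layer:
  proliferation/survival statements are read directly from pmTORC1 and
  pmTORC2 as proxies.
* SBML export covers species, parameters, reactions and kinetic laws;
  import and round-tripping are out of scope.
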