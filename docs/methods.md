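# Methods

This note documents the models implemented in `darkox`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Chamber flux inference

A benthic chamber seals area *A* (default 484 cm², a 22 cm square) with a
water column of depth *h* measured post-recovery (mean of four
measurements), so *V = A·h/1000* litres. The estimator reports:

- **initial O₂** — median over the first 5 min after sealing. The sealing
  instant itself is a single noisy sample; a short median window is robust
  without mixing in meaningful production (at 10-s logging, 30 samples).
- **maximum O₂** — maximum of a centred 5-min rolling median computed over
  full windows only. A plain maximum over ~17,000 noisy samples carries an
  extreme-value bias of roughly σ√(2 ln n) ≈ 2 µmol l⁻¹ at σ = 0.5, which
  is a pure sensor artifact; the rolling median suppresses it while
  remaining slope-consistent on monotone traces (the median of a symmetric
  window on a linear segment is its centre value), so noise-free recovery
  stays exact.
- **rates** — both a max-based rate ΔC·h/t_max and the least-squares
  regression slope of the sealed, stirred segment are reported. Production
  in these incubations saturates, so the two differ and neither is
  privileged: the max-based form is the headline (it matches how total net
  change is defined), the regression slope is the better estimate of an
  early-incubation rate. The rate denominator is the time from sealing to
  the maximum rather than the fixed incubation length, which makes the
  nonlinear plateau explicit.
- **classification** — net producer / net consumer / neutral by the sign of
  ΔC against a configurable tolerance (default 0, i.e. any rise counts).

Chambers whose doors failed to close have unknown volume; they keep all
concentration-based fields and a flag, and are excluded from totals and
areal rates.

**Dilution correction.** Each syringe sampling event entrains ambient
water: C⁺ = (C⁻(V−v) + C_amb·v)/V with v = 50 ml. The inversion adds the
implied step (C⁻ − C_amb)·v/V back to every later sample, estimating C⁻
from the last observed sample before the event (the observed trace *is* the
physical concentration each event acted on, so steps from the raw trace
compose to the exact inverse). Correction is **off** for headline results —
the dips are small and the uncorrected trace is what was measured — and
available as a sensitivity mode; with it on, noise-free round trips are
exact to machine precision.

**Decline-based SCOC.** For the minority of chambers with a steady O₂
decline, SCOC = −slope·h/100 (mmol m⁻² d⁻¹); a non-negative trend is an
error directing the user to the net-change estimator.

## Optode processing

Two-point, multi-temperature calibration at 0% and 100% saturation
(canonically 1.2, 7, 18, 30 °C). The raw-signal model is affine per
temperature with linear interpolation of offset and gain in temperature.
Commercial optodes convert a luminescence phase through a Stern–Volmer-type
transfer function with proprietary constants; a two-point calibration pins
any monotone transfer at its anchors, so the affine abstraction preserves
the calibration contract (exact at both anchors at every calibrated
temperature) while remaining testable. The 100% reference concentration
comes from the Garcia & Gordon (1992) solubility refit of the Benson &
Krause data (ml l⁻¹ coefficient set × 44.6596 µmol per ml at STP).

Pressure correction is multiplicative, 3.2% per 1000 dbar by default
(configurable); it vanishes at the surface. Drift is estimated from
repeated calibrations as the mean concentration discrepancy at reference
conditions divided by elapsed days (positive = the sensor reads higher
later); drift *correction* is off by default because lander-scale drift is
typically a fraction of a µmol l⁻¹ per day — negligible against
multi-hundred-µmol signals — but can be switched on.

Winkler duplicates are summarised as per-sample means plus the
|difference| statistics (mean ± SE, n), and compared against the optode as
100·(optode − Winkler)/optode matched within a 60-s window, positive when
the Winkler value is lower (syringe samples degas during recovery, so a
positive offset is expected).

## Microprofile SCOC

Fick's first law J = φ·D_s·dC/dz with the Boudreau tortuosity correction
D_s = D₀/(1 − ln φ²). D₀ defaults to 1.18 × 10⁻⁵ cm² s⁻¹ (O₂ in seawater at
1.6 °C, S = 35, interpolated from the Schulz & Zabel (2006) tabulation).
Porosity is a required user input: it is site-specific and no default is
claimed. Unit bookkeeping: J [mmol m⁻² d⁻¹] = φ · D_s[cm² s⁻¹] · 8640 ·
|dC/dz| [µmol l⁻¹ mm⁻¹].

The sediment–water interface — the turning point where the quasi-constant
overlying-water segment gives way to depletion — is located by a
two-segment least-squares changepoint fit (constant above, line below).
This is the maximum-likelihood turning point for exactly this profile
shape under i.i.d. noise; a smoothed second-difference extremum is kept as
an alternative (`method="curvature"`) and a manual index override mirrors
the traditional hand pick. At the study's step size (0.05 mm) and
per-replicate noise (0.5 µmol l⁻¹), a raw curvature statistic has
sub-unity signal-to-noise per point, which is why the changepoint fit is
the default.

The gradient is fitted over 0.5 mm (11 points) just below the interface —
deep enough to average noise, shallow enough to stay within the
quasi-linear zone. A positive gradient (O₂ increasing downward) is flagged
rather than rejected. Diffusive-boundary-layer fluxes are not attempted;
the sediment-side gradient is the target quantity.

## Radiolysis

Per-inventory kinetics as in the README; numerically, the decayed fraction
uses `expm1`, since λt over a 48-h incubation is ~10⁻¹²—10⁻¹³ and
`1 − exp(−λt)` would lose four significant digits there. Masses are in
grams end to end (the expression is dimensionally consistent in grams when
Q and the molar masses are in grams); conversion to µmol l⁻¹ happens only
at the chamber-volume boundary.

Defaults assume secular equilibrium: E_a is the full decay-chain energy per
parent decay (51.7, 46.4, 42.6 MeV for the U/Th chains; 1.31 MeV for ⁴⁰K),
with parent-only values available. G(O₂) defaults are literature-derived
(half of G(H₂): 0.65 molecules/100 eV for the α-dominated chains, 0.22 for
⁴⁰K) and are ordinary configuration inputs — users with measured
inventories should supply their own E_a/G values. The nodule boundary layer
is treated as fully integrated with the chamber water: all emitted
radiation energy within the particle stopping distance contributes, with no
geometric attenuation. The full multi-reaction radiolysis network behind
published G-values is deliberately out of scope; only the summary
expression is implemented. The packaged inventory table
(`data/synthetic_inventories.csv`) is a synthetic, literature-plausible
stand-in for a measured chamber inventory; with it, the 48-h radiolytic
contribution is of order 10⁻⁶ µmol l⁻¹ — negligible against observed
signals, which is the scientific point of the comparison.

## Artifact screen

- **Plastic intrusion** scales a published worst-case release (20.66
  µmol l⁻¹ from 428 cm² of polyoxymethylene over 48 h in hypoxic water)
  linearly in exposed area (lid + four wall strips wetted to the water
  depth) and duration. The published per-area rate (0.02 µmol cm⁻² d⁻¹)
  route is available as a cross-check. The bound is an overestimate in
  oxygenated chambers.
- **Bubble dissolution** uses a quasi-static Epstein–Plesset-type closed
  form t = R²·c_gas/(2D·ΔC) with the gas at hydrostatic + atmospheric
  pressure (1 dbar per metre, configurable) and Henry's-law interfacial
  concentration scaled with total pressure. The model neglects surface
  tension, bubble rise and convective enhancement, so in stirred chambers
  it errs long; it is property-tested (R² scaling, monotone in depth), not
  claimed identical to any particular published bubble model, and its
  output is advisory.
- **Core-tube leaks** convert an observed concentration rise in a sealed
  N₂-sparged tube to an areal rate (ΔC·h/100)/(t/24) and express it as a
  percentage of a reference DOP rate.

## Electrochemistry and statistics

Voltage surveys subtract the electrode-only seawater background from each
replicate. Box-whisker summaries use Tukey hinges (medians of the halves,
the overall median excluded from both halves when n is odd). OER
feasibility compares the maximum corrected potential to
1.23 V + overpotential − mechanism reduction, with an inclusive boundary
(observed = required counts as feasible); the lattice-oxygen-mediated
reduction is a free parameter since its magnitude is
catalyst-specific ("several hundred millivolts" in the literature).

One-way ANOVA is computed from the sum-of-squares decomposition directly so
the degenerate all-equal case returns F = 0, p = 1 rather than NaN.
Spearman correlation uses average ranks; its p-value is the exact two-sided
permutation probability for n ≤ 9 (at n = 9, 362,880 orderings — still
cheap) and the t-approximation with n − 2 degrees of freedom above that.
One-way designs per factor are used throughout; taxon tables aggregate ASV
relative abundances by lineage rank with per-sample totals conserved.

## Synthetic data generator

The generator emulates the phenomenology of abyssal nodule-field chamber
incubations: initial O₂ drawn from 185.2 ± 2.9 µmol l⁻¹, a monotone
saturating rise over 47 h, a flat reading while the stirrer is off (first
1 h), mass-balance dilution dips at syringe events (28, 38, 47 h; 50 ml),
linear sensor drift (0.27 µmol l⁻¹ d⁻¹), i.i.d. Gaussian noise
(0.5 µmol l⁻¹), optional logging gaps (samples removed, never
interpolated), and a constant ambient control trace. Default rates are
SCOC 0.7 and gross production 4.2 mmol m⁻² d⁻¹ (net 3.5, the centre of the
observed range); the pipeline demo spans net rates ~1.7–8 mmol m⁻² d⁻¹.

Saturating production is modelled as exponential relaxation: cumulative
concentration gain ΔC(t) = m₀·τ·(1 − e^(−t/τ)) with τ = duration/s for
shape parameter s (s = 0 gives a linear trend). Any smooth monotone
damping would be defensible; the single-parameter exponential was chosen
because it is invertible, has an interpretable asymptote, and reduces
exactly to the linear case.

Microprofiles are constant above the interface and decline linearly at
gradient J/(φ·D_s) over the upper half of the profiled sediment thickness,
then relax along a slope-matched exponential tail. Five replicate readings
per depth carry the per-replicate noise and are averaged, as the profiler
does. The taxon generator assigns the designated taxon's *relative*
abundance directly through a Gaussian rank blend so the target Spearman
correlation with production rates survives row normalisation (exact
monotone coupling at |ρ| = 1).

Randomness: every generator spawns independent child streams from the
single root seed via `numpy.random.SeedSequence.spawn` in a fixed order, so
identical seed + config are bit-identical and streams never collide across
chambers or stages.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: hydrodynamic chamber mixing and bow-wave
disturbance; pressure- and temperature-dependent raw optode signals
(synthetic series are in concentration units; calibration is tested on its
own affine fixtures); correlated or heavy-tailed sensor noise (the noise
spectrum of the real instruments is uncharacterised, i.i.d. Gaussian is an
assumption); spatial heterogeneity between chambers beyond the net-rate
ladder; and any mechanistic link between voltages, nodule properties and
production.

## Problem sizes and numerical choices

Monte-Carlo guarantees are stated over 100 seeded replicates at the study
noise level (chamber: ≥95/100 within 5% of the generating net rate;
microprofile: ≥95/100 within 10%, mean error < 5%; interface detection:
≥90/100 within 4 grid steps). These sizes give stable pass/fail behaviour
while keeping the full suite in seconds. Tolerances of 10⁻¹²–10⁻⁶ relative
mark exact identities (oracle equivalence, round trips); percentage bands
mark statistical recovery. Ties in the rolling-median argmax resolve to the
earliest sample; the changepoint search excludes the first five points
(the water column must exist) and the last two (a line needs two points).

## Known limitations

- The affine optode model cannot capture genuine Stern–Volmer curvature
  between calibration anchors; with anchors at 0% and 100% the interpolation
  error is second-order but not zero.
- The max-based DOP rate is a time-average to the maximum; under strongly
  saturating production it undershoots the initial instantaneous rate by
  construction (both rates are reported for this reason).
- The bubble model is deliberately minimal and its absolute times should
  not be over-interpreted; only its scalings are load-bearing.
- The radiolysis module evaluates the summary kinetic expression; it does
  not recompute G-values from reaction networks, and its output is only as
  good as the supplied inventories.
- Exact Spearman p-values are limited to n ≤ 9 by factorial growth; beyond
  that the t-approximation is used (and documented in results).
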