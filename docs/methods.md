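# Methods

This note documents the models implemented in `petkinlab`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Turbidimetric heterogeneous kinetics

Enzymatic PET-nanoparticle hydrolysis is a surface-erosion process. The
blank-corrected OD600, normalised to its initial value (relative
turbidity τ/τ₀), tracks the remaining particle cross-section; for
shrinking spheres the square root of τ/τ₀ declines linearly in time, and
the initial decline rate v saturates hyperbolically in enzyme
concentration because catalysis requires adsorption to a finite particle
surface:

v([E]) = k_τ·K_A·[E] / (1 + K_A·[E]).

Assumptions: constant particle number, sub-monolayer enzyme coverage (at
high loads adsorption can exceed the monolayer and rates fall off the
curve — such points can be excluded only via the explicit
`exclude_above` option, never silently), and a substrate load inside the
range where rates are substrate-independent.

**Initial-rate extraction.** The observable is noisy and has a 1–2 min
mixing/lag phase, so the slope of (τ/τ₀)^½ is taken from a data-driven
window: points before the configured lag (default 1.5 min, the midpoint
of the typical 1–2 min range) and points where turbidity has fully
decayed to zero are excluded; all contiguous windows covering at least
20% of the remaining span (and ≥ 5 points) are scanned, and among those
with linear R² ≥ 0.98 the longest wins (ties: earliest, then higher R²).
If no window qualifies, the whole post-lag span is used. Requiring a
minimum window span matters: with realistic noise a handful of
consecutive points can reach R² ≥ 0.98 with an arbitrary slope, while
long qualifying windows exist only inside the genuinely linear region. A
positive slope is clamped to zero and flagged rather than reported as a
negative rate.

**Saturation fit.** Nonlinear least squares (Levenberg–Marquardt) on
(log k_τ, log K_A) — the log-parameterisation enforces positivity without
constraints. Initialisation: k_τ from the maximum observed rate, K_A from
the reciprocal of the concentration nearest half-maximum. Standard errors
come from the Jacobian-based covariance at the optimum (delta method back
to the natural scale); R² is 1 − SS_res/SS_tot. Weighting is uniform by
default; when measurements carry known standard deviations (replicate
SDs, or the generator's declared noise), per-point 1/SD weights restore
correct error calibration under the relative-noise regime — with them,
2-standard-error intervals cover the true parameters at their nominal
rate in the recovery suite.

## Thermal stability

**Melt curves.** Ellipticity ramps are fitted with a two-state Boltzmann
sigmoid between linear folded/unfolded baselines (six parameters: T_m,
width, two intercepts, two slopes). This is the fewest-parameter model
that handles sloping baselines and is stable on noisy ramps; an enthalpy
(van 't Hoff) parameterisation adds nothing for T_m extraction.
Baselines initialise from the outer 15% of the ramp, T_m from the
half-unfolded point. A fit whose transition amplitude is below 10% of the
signal range, or whose T_m falls outside the scanned range, is rejected
("monotone baseline only"). The fit is invariant under affine transforms
of the signal axis, so raw machine units are fine.

**Inactivation.** Residual activity normalised to t = 0 is fitted with
a(t) = exp(−k_in·t) by direct nonlinear least squares; a log-linear
regression only supplies the starting value, because fitting logged noisy
data biases the rate. Points below a 1% detection floor are excluded. A
constant series yields k_in = 0 with the half-life reported as infinite
(flag, not a number). Comparative reports give ΔT_m against a designated
reference variant and fold-changes of k_in in both directions, labelled.

## Bioconversion quantification

Product concentration c = A·dilution/(ε·path) with ε₂₄₀ = 13.8 mM⁻¹ cm⁻¹
for the mixed aromatic pool (MHET/TPA/BHET are spectrally unresolved at a
single wavelength and are treated as one aromatic-equivalent pool).
Molar depolymerization yield divides the product pool by the theoretical
repeat-unit concentration, substrate (mg/mL) / MW_repeat × 1000, with
MW_repeat defaulting to 192.17 g mol⁻¹ (C₁₀H₈O₄). The basis mass is
configurable because the effective monomer mass of a mixed MHET/TPA pool
is ambiguous: 10.6 mM of products on 9 mg/mL PET is 22.6% on the
repeat-unit basis but a few points higher on other defensible bases;
the package computes, it does not force agreement with any particular
rounding. Yields above 100% are flagged, never clamped. The specific
rate over a user-stated window is products(t_end) − products(t_start)
divided by enzyme load and elapsed days (µM µg⁻¹ day⁻¹); multiplying by a
product-equivalent molar mass (default TPA, 166.13 g mol⁻¹) and dividing
by 24 converts to g L⁻¹ g_enzyme⁻¹ h⁻¹.

## Plate screening

Relative activity anchors each well to the on-plate controls:
(mean_neg − A540)/(mean_neg − mean_parent) × 100. The score is invariant
under any common gain/offset of the plate reader and strictly monotone in
acidification. Hit calling uses a margin of 2 pooled-control SDs on the
activity scale (no absolute threshold is defensible without a pH
calibration); control aggregation is the mean, with a median option.
Flagged wells are excluded via the layout role `empty`, never imputed.

## Library statistics

Degenerate codons expand exhaustively over the IUPAC alphabet and are
translated with the standard genetic code (table 1; the host is
*E. coli*). For n independent unbiased clones, per-residue coverage is
1 − (1 − p_aa)ⁿ; the probability of seeing all 20 amino acids uses
inclusion–exclusion, grouped by codon multiplicity so the 2²⁰ subset sum
collapses to a few hundred terms. Stops are reported but are not
coverage targets (a stop at the randomised position is a non-variant).
The sample-size answer (`clones_for_target`) is the smallest n at which
the rarest amino acid is seen with the requested confidence; for NNK at
95% this is 95 clones, which is why one 96-well plate per position is the
field's rule of thumb. Primer synthesis bias is out of scope.

## SSM-position triage

A docked pose is catalytically competent when one of its ester groups
puts the ester carbon < 4 Å from the catalytic Ser Oγ and the carbonyl
oxygen < 4 Å from both oxyanion-hole backbone amides (defaults Ser160,
Tyr87/Met161, mature-protein numbering; all configurable, with an offset
option for full-length numbering). Distance comparison is strict at the
threshold. Pose clustering is greedy leader clustering in docking-score
order at 1 Å ligand-heavy-atom RMSD, computed without superposition since
poses share the receptor frame. Hotspots are residues with mean
per-residue binding-energy contribution ≤ −1 kcal mol⁻¹ (inclusive);
conserved positions have relative evolutionary rate < 1.2 (exclusive,
the sequence-average convention). Selection = hotspot ∧ ¬conserved ∧
¬excluded; exclusions are a user-supplied list each requiring a reason
string, and are never hardcoded. Docking, MD, binding-energy and
conservation-rate computation themselves are upstream tools; this module
consumes their tabular/coordinate outputs.

## Synthetic-data generator

The generator produces every input above from explicit ground truth and
one seeded `numpy.random.Generator` (bit-reproducible; the seed is
recorded in output metadata). Noise is additive Gaussian with SD
proportional to the local signal, default 2% relative — typical of plate
readers and spectrophotometers; for melt curves the reference signal is
the transition amplitude since raw ellipticity crosses zero. Defaults
encode the standard assay conditions: 10 s sampling, 20 min traces,
1.5 min lag, enzyme series 0.002–0.08 mg/mL, ~94 µg/mL nanoparticle
load mapped to an initial blank-corrected OD600 of 1.0 over a 0.05
blank, melt ramps 30–75 °C in 0.5 °C steps with a 2 °C transition width.
The plate generator maps relative activity linearly between the control
means; the real dye response is sigmoidal in pH, so extreme
extrapolation is less faithful than the screened range. The structural
fixture realises requested catalytic distances exactly in a minimal
receptor (anchor atoms plus one Cα per listed residue) — it is a
synthetic geometry scaffold, not a protein model.

What passing tests show, and what they do not: recovery on these
synthetic inputs demonstrates that the estimators are unbiased and
correctly calibrated under the stated noise model. Real data add
systematic effects the generator deliberately omits — particle
sedimentation and scattering physics, monolayer over-saturation at high
enzyme loads, partial unfolding reversibility, pH drift in weakly
buffered plates, codon synthesis bias — so passing here validates the
analysis, not the assay.

## Problem sizes and runtimes

Recovery suites use 200 seeded datasets (6 concentrations in triplicate
at 5% relative noise for kinetics; 6 time points for decays), chosen so
the whole test suite completes in a few seconds while medians and
coverage rates are stable. The acceptance script fits 3 variants × 6
noise-free traces (121 points each) plus one 91-point melt curve; it
runs in about a second.

## Known limitations

* The linear-window heuristic assumes the decline is genuinely linear
  after the lag; strongly curved early phases (very high rates at coarse
  sampling) shorten the usable window and inflate the rate SE.
* The Langmuir fit treats concentrations as exact; pipetting error is
  not propagated.
* Melt fitting reports an apparent T_m; no scan-rate correction or
  unfolding ΔG is attempted.
* The single-wavelength bioconversion assay cannot speciate products;
  all yields inherit the basis-mass ambiguity documented above.
* Coverage math assumes unbiased, independent codon sampling.
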