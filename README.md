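# petkinlab

Quantitative analysis for the engineering of PET-hydrolysing enzymes
(PETases, EC 3.1.1.101): turbidimetric heterogeneous-catalysis kinetics,
thermal-stability fits, bioconversion yields, 96-well screening scores,
degenerate-codon library statistics and docking-based selection of
site-saturation-mutagenesis (SSM) positions. It is aimed at enzyme
engineers and biocatalysis labs who run nanoparticle turbidity assays, CD
melts, Phenol-Red plate screens and PET depolymerization reactions and
want the number crunching reproducible and tested — including a seeded
synthetic-data generator that stands in for every wet-lab measurement.

## The models

**Turbidimetric kinetics.** Hydrolysis of suspended PET nanoparticles is
followed as an OD600 decrease. The relative turbidity

τ/τ₀ = |OD₆₀₀ − OD₆₀₀°|ₜ / |OD₆₀₀ − OD₆₀₀°|₀

(OD₆₀₀° = buffer blank) is a proxy for the remaining particle
cross-section; after a short lag, (τ/τ₀)^½ declines linearly and its
initial rate follows a Langmuir-type rate law in enzyme concentration,

−d(τ/τ₀)^½/dt = k_τ·K_A·[E] / (1 + K_A·[E]),

with K_A (mL mg⁻¹) the enzyme–particle adsorption equilibrium constant
and k_τ (min⁻¹) the maximal square-root-turbidity decline rate at surface
saturation. `LangmuirKinetics(...).fit()` returns a results object with
estimates, standard errors, R², `summary()` and `plot()`.

**Stability.** CD melts at 222 nm are fitted with a two-state Boltzmann
sigmoid between linear baselines (midpoint = T_m); residual-activity time
courses with first-order loss a(t) = exp(−k_in·t) (half-life ln 2/k_in).
`stability_report` compares variants (ΔT_m, fold-changes of k_in).

**Bioconversion.** Soluble aromatic products are quantified from A₂₄₀ via
Beer–Lambert (ε₂₄₀ = 13.8 mM⁻¹ cm⁻¹), turned into depolymerization yields
(molar repeat-unit basis, 192.17 g mol⁻¹, or mass basis) and
enzyme-specific rates, including the µM µg⁻¹ day⁻¹ → g L⁻¹ g⁻¹ h⁻¹
conversion.

**Screening, libraries, hotspots.** Plate wells are scored on a
control-anchored scale (negative control = 0%, parent = 100%); NNK/NNS
codon schemes are expanded exhaustively and screening sample sizes
computed by inclusion–exclusion; SSM positions are selected from docked
poses (catalytic-competence distance filter, 1 Å RMSD leader clustering),
per-residue binding-energy tables (hotspot ⇔ mean ΔG_bind ≤ −1 kcal
mol⁻¹) and per-site conservation rates (conserved ⇔ rate < 1.2), with
explicit, reasoned knowledge-based exclusions.

## Worked example

```python
from petkinlab import synthetic as syn, kinetics as kin

gt = syn.KineticGroundTruth(k_tau=0.076, K_A=37.95)   # parent enzyme
cfg = syn.SimulationConfig(seed=0, noise_sd_rel=0.02)
rng = cfg.rng()
points = []
for e in gt.enzyme_concs:                # 0.002 ... 0.08 mg/mL
    trace = syn.simulate_turbidity(gt, cfg, e, rng=rng)
    series = kin.compute_relative_turbidity(trace)
    points.append(kin.estimate_initial_rate(series))
print(kin.fit_langmuir_kinetics(points).summary())
```

```
               Langmuir turbidimetric kinetics
==============================================================
model                            v = k_tau*K_A*[E]/(1+K_A*[E])
n points                                                     6
R^2                                                     0.9998
--------------------------------------------------------------
parameter                 estimate         std err
--------------------------------------------------------------
k_tau (1/min)            0.0755211       0.0007803
K_A (mL/mg)                38.3874          0.9506
==============================================================
```

Six OD600 traces with 2% instrument noise were simulated from the rate
law at k_τ = 0.076 min⁻¹, K_A = 37.95 mL mg⁻¹; the pipeline recovers both
parameters within one standard error. With `noise_sd_rel=0` the recovery
is exact to machine precision.

The same objects are reachable from the command line:

```bash
petkinlab simulate turbidity --seed 0 --out traces/
petkinlab kinetics fit --traces 'traces/*.csv' --out report.json
petkinlab library --scheme NNK --clones 94 --confidence 0.95
```

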