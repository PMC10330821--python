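# granchan

Quantitative analysis of secretory-granule anion channels.

Dense-core secretory granules (DCSGs) of neuroendocrine cells need anion
conductances for ion homeostasis, and chromogranin B (CHGB) — a granin that
exists in both soluble and membrane-bound ("dimorphic") forms — reconstitutes
a large-conductance, highly Cl⁻-selective channel. Establishing that claim
takes four quantitative workflows, all implemented here as a tested library:

1. **Immunogold membrane-distance statistics** (`granchan.immunogold`,
   `granchan.pipeline`): segment gold labels in calibrated electron
   micrographs (band-pass enhancement → Otsu → hole filling → watershed),
   classify them by cross-section area (< 20 nm² noise, 20–65 nm²
   insulin-class 6-nm gold, ≥ 65 nm² CHGB-class 12-nm gold, eccentricity
   > 0.75 removed), assign them to annotated granule rings extended outward
   by 20 nm, and measure the signed distance *d* of each centroid to its
   granule membrane (*d* > 0 inside). Distances are binned at 20 nm,
   decomposed with a one- or two-component Gaussian-mixture EM, and compared
   with the antibody-geometry bounds on how far a gold bead can sit from a
   membrane epitope.
2. **Electrodiffusion selectivity** (`granchan.permeation`): Nernst
   potentials E = (RT/zF)·ln(C_cis/C_trans), the Goldman–Hodgkin–Katz (GHK)
   reversal relation for monovalent mixtures, a bisection solver for
   permeability ratios from measured reversal potentials, per-ion GHK current
   shares, and the charge-balance estimates for an exocytosis site (ion
   counts in a femtoliter volume, the charging potential of a µm-scale
   membrane patch).
3. **Current-record analysis** (`granchan.channel_records`): OLS I–V fits
   (slope conductance, reversal), chord conductance I/(V−E_rev),
   half-amplitude-threshold idealization of two-level single-channel traces,
   dwell-weighted unitary currents, channel counting, single-exponential
   inactivation fits, whole-cell current-change rates, and Welch *t* group
   comparison with Bonferroni adjustment.
4. **Flux kinetics** (`granchan.flux_kinetics`): normalization of
   valinomycin-triggered light-scattering flux traces and nonlinear
   least-squares fitting of the Hill block relation
   I([L]) = 1/(1 + ([L]/k_D)^n).

Every analysis is driven by seeded synthetic-data generators
(`granchan.synthgen`) that emulate the raw data with known ground truth:
immunogold fields with two gold sizes and a shell/core CHGB mixture,
two-level Markov channel traces with optional slow inactivation, Hill-blocked
flux decays, fluorescent surface-puncta images, and compound-Poisson
whole-cell conductance staircases.

## Worked example

```python
import granchan as gc

# selectivity from a bilayer recording in 150/30 mM KCl at 297.1 K
print(gc.nernst_potential(-1, 150, 30))        # -41.204985746352655  (mV)
cond = gc.RecordingCondition((gc.IonSpecies("K", 1, 150, 30, 1.0),
                              gc.IonSpecies("Cl", -1, 150, 30, 1.0)))
print(gc.solve_permeability_ratio(-40.5, cond, "Cl", "K"))
# 171.7266892840723  -> P_Cl/P_K well above 100: a highly anion-selective channel

# Hill fit of a synthetic chloride-inhibition flux series (truth kD 0.47 mM)
traces, table = gc.make_flux_series(gc.FluxSimParams.chloride_defaults(seed=1))
fit = gc.fit_hill(table)
print(fit.kD, fit.n)                           # 0.4488348248507594 0.9660089835010602

# full immunogold pipeline on the default synthetic dataset (324 granules)
data = gc.make_em_dataset(gc.EMFieldParams(seed=1), n_fields=3)
report = gc.run_em_pipeline([(img, rings) for img, rings, _ in data], seed=1)
print(report.summary["chgb_fraction_within_40nm"])   # 0.4154  (~40% of CHGB near the membrane)
print(report.summary["chgb_proximal_peak_nm"])       # 24.24   (membrane-proximal CHGB mode, nm)
print(report.summary["insulin_peak_nm"])             # 105.72  (insulin core mode, nm)
print(report.summary["mean_equivalent_diameter_nm"]) # 192.90  (mean granule diameter, nm)
```

The first block reproduces the closed-form selectivity numbers: a five-fold
KCl gradient puts the Cl⁻ equilibrium at −41.2 mV, and a measured reversal of
−40.5 mV implies a Cl⁻:K⁺ permeability ratio above 100. The Hill fit recovers
the generator's dissociation constant within 5%. The pipeline block runs
segmentation → classification → ring assignment → distances → mixture
decomposition over three pooled synthetic fields: roughly 40% of CHGB-class
gold lies within −20…+40 nm of the granule membrane with a proximal mode near
25 nm, while insulin-class gold concentrates deep in the granule core — the
dimorphic-versus-core-only contrast the immuno-EM analysis is designed to
quantify.

A thin CLI mirrors these calls: `granchan ghk --cis K:150,Cl:150 --trans
K:30,Cl:30 --erev -40.5`, `granchan simulate-em`, `granchan analyze-em`,
`granchan simulate-flux`, `granchan fit-hill`.

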