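# Methods

This note documents the models behind `granchan`, the defaults that matter,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Electrodiffusion (permeation)

Potentials use the trans-referenced convention E = (RT/zF)·ln(C_cis/C_trans),
the unique sign choice that makes a 150/30 mM gradient give −41.2 mV for Cl⁻
and +41.2 mV for K⁺ simultaneously. The default temperature is **297.1 K**:
nominally the recordings are at room temperature, but ±41.2 mV for a
five-fold gradient implies RT/F ≈ 25.6 mV (≈24 °C), so the default is chosen
to be self-consistent with those potentials; temperature is an explicit
argument everywhere.

The GHK reversal relation and per-ion current equation are implemented for
monovalent ions only; divalents are rejected rather than approximated (the
charge-balance estimates handle valence explicitly instead). The
permeability-ratio solver brackets log r over ±40 and bisects (`brentq`,
machine tolerance); the solve/eval round trip is exact to 10⁻⁶ relative over
randomized conditions. Note that a reversal potential within ~1 mV of the
permeant ion's Nernst limit makes the solved ratio numerically fragile — the
ratio grows without bound as the limit is approached — so downstream checks
treat such ratios as lower bounds (r > 100), not point estimates. Per-ion
currents use the analytic first-order limit for |zFV/RT| < 10⁻¹⁰ so shares
are continuous through 0 mV.

Charge estimates: N = N_A·C·V ions in a local volume (10 µM in 40 fL ≈
2.4×10⁵ divalent ions), and V = N·|z|·e / (C_spec·π(d/2)²) for the potential
those ions impose on a circular membrane patch (defaults: 4 µm diameter,
1.0 µF/cm²) — about 0.6 V, the charge-compensation argument for why anion
influx must accompany Ca²⁺ entry at a release site.

## Current records

* I–V fits are ordinary least squares; E_rev = −intercept/slope with
  delta-method standard errors; chord conductance I/(V−E_rev) is exposed
  separately from the fitted slope because macroscopic records mix both.
* Idealization thresholds at baseline + amplitude/2 (sign-aware). The
  baseline defaults to the mode of a 200-bin all-points histogram. Dwells
  shorter than 2 samples are absorbed shortest-first into their neighbours;
  segments always partition the trace. At SNR 5 this assigns ≥ 99% of
  samples to the true state and recovers unitary amplitudes with < 2% bias.
* Unitary current is dwell-weighted (mean open minus mean closed sample),
  invariant to baseline offsets; the reported spread is that of per-opening
  amplitudes.
* Channel count = round(macroscopic/unitary conductance), half away from
  zero; with ~600 pS chord conductance and ~110 pS channels this gives 5.
* Inactivation fits I(t) = A·e^(−t/τ) + C with `curve_fit`, τ bounded in
  (0, 100×window]; non-decaying input is returned flagged, never raised.
* Group comparison is Welch's two-sided t (the robust default when equal
  variances cannot be assumed) with Bonferroni adjustment, capped at 1;
  two identical zero-variance samples return p = 1 by convention.

## Flux kinetics

The Hill block I([L]) = 1/(1+([L]/k_D)^n) is fitted by least squares over
(log k_D, log n) — positivity and conditioning — with a multi-start grid
(7 log-spaced k_D starts × n starts 0.5/1/2), bounds k_D ∈ [10⁻⁶, 10³] input
units, n ∈ [0.1, 10]. Responses are clipped to [0, 1.05] (noise can push
them slightly above 1) rather than discarded. Optional case-resampling
bootstrap gives percentile CIs. Trace amplitudes are plateau-based: baseline
is the pre-trigger window mean, plateau the final 10% of samples, the
solvent control's amplitude is subtracted, and the series is normalized to
its zero-inhibitor (lowest-concentration) condition — plateau amplitude
rather than initial rate, matching a percent-inhibition presentation.

## Synthetic immunogold fields

The generator emulates pooled immuno-EM experiments on pancreatic β-cell
granules:

* granule radii truncated-normal (mean 90 nm, s.d. 40, bounds 40–220 nm;
  mean diameter ≈ 196 nm), laid out on a jittered grid whose cell size
  (2·R_max + 60 nm) makes collisions impossible;
* expected label counts per granule scale as (R/98)² — larger granules carry
  more labels — with rates 3 (CHGB-class) and 8 (insulin-class) at R = 98 nm;
* insulin labels sit in the dense core: center offset s half-normal
  (σ = 12 nm), distance d = R − s, so truncation at the granule is automatic;
* CHGB labels are a mixture: with probability 0.48 membrane-proximal
  (truncated normal, mean 25 nm, s.d. 16 nm, bounds [−20 nm, R]), otherwise
  the same core model — the generative counterpart of a dimorphic protein;
* gold beads are rendered as dark anti-aliased disks (6/12 nm) on a bright
  16-bit background (30000 ± 800 counts, beads 20000 counts darker).

**Steric exclusion.** Gold beads are solid, so labels cannot interpenetrate;
placement keeps each drawn distance, resamples the azimuth (innermost bead
first, largest clearance), and nudges a bead radially only when no azimuth is
free. The truth table records the rendered geometry. The spreading this
forces on crowded cores is physical and unavoidable: it lowers the realized
mean insulin distance by ~2–3 nm relative to the unconstrained half-normal
model (whose population mean is E[R³]/E[R²] − 12·√(2/π) ≈ 110.5 nm under the
R²-weighted counts). A single Gaussian fitted to the measured insulin
distances therefore sits near 105–108 nm — the structural ceiling of this
generative model, several nm below the 117 nm a real dataset can show, and
the measured value tracks the generator truth to within ~1 nm, so the gap is
a property of the model, not of the measurement chain.

The default dataset is 324 granules split over three fields (three pooled
experiments, ~25 Mpixel each at 1 nm/px); this size keeps a full pipeline
run under a minute on one CPU while giving ~1000 CHGB-class and ~2700
insulin-class particles.

**What the generator does not emulate:** real EM texture (stain granularity,
ice), the 70-nm section geometry, non-circular granule outlines, and
antibody-displacement jitter (distances are those of the bead centers, so
the antibody-geometry bounds are commentary, not part of the generative
model). Passing pipeline tests therefore show the measurement chain is
unbiased on resolvable, controlled contrast — not that it would segment
real micrographs, where the published workflow used a trainable classifier.

## Immunogold measurement chain

Enhancement is a deterministic difference-of-Gaussians band-pass (σ 0.5 and
20 nm) on the inverted image, rescaled to [0, 1] — a parameter-free stand-in
for trainable pixel classification, appropriate because synthetic contrast
is controlled. Then: Otsu threshold on a 256-bin histogram, hole filling,
watershed seeded at distance-transform maxima ≥ 3 nm apart, border-touching
components removed. The σ = 20 nm background scale and 3 nm seed separation
were set by truth-recovery on dense fields: a tighter band-pass suppresses
the interiors of crowded bead clusters (losing core labels and biasing the
insulin distribution), a looser one bridges touching beads into blobs; the
chosen pair recovers ≥ 99% of labels with correct class on noise-free fields
and tracks the truth distance distributions without detectable bias at the
default noise. Two beads closer than ~1 nm surface-to-surface remain
unresolvable in principle at 1 nm/px.

Features come from moment-based region properties (areas in nm², weighted
centroids on the enhanced map, eccentricity √(1−(minor/major)²) of the
moment-fit ellipse). Classification uses the published thresholds with both
area boundaries inclusive toward their class (20 nm² → insulin, 65 nm² →
CHGB). Ring assignment uses shapely polygons dilated by 20 nm; a particle in
two extended rings goes to the nearer boundary (the original analysis made
this call manually). Signed distance is point-to-polyline with interior
positive — the reading under which a "−20 to 0 nm" bin means gold just
outside the granule edge. The "within 40 nm" fraction counts −20 ≤ d ≤ 40,
bounded below by the 20-nm analysis extension.

The 1-D Gaussian-mixture EM runs 5 restarts (one quantile split, four random
two-point starts), tolerance 10⁻⁸ on the log-likelihood, 500 iterations max,
variances floored at 10⁻⁶; monotone non-decrease of the log-likelihood is
asserted every step. BIC (−2LL + p·ln n, p = 3k−1) does the k = 1 vs 2 model
choice, and for k = 2 a Welch t between posterior-assigned subgroups gives
the mode-separation p-value. A symmetric shell model under-produces the
observed mass just outside the membrane (~3% in the −20…0 nm bin versus ~6%
in real data); this is a documented deviation and deliberately not an
acceptance statistic.

## Other generators

* **Channel traces**: per-channel two-state Markov paths simulated exactly
  (exponential dwells), sampled on the grid; optional irreversible
  inactivation clock at rate 1/τ per channel; current = n_open·g·(V−E_rev)
  + Gaussian noise. Seeds spawn per channel, so adding channels never
  reshuffles existing paths.
* **Flux traces**: baseline − A·Hill([L])·(1−e^(−t/τ)) with a 10 s
  pre-trigger window, τ = 20 s, amplitude 0.4, amplitude noise s.d. 0.02 on
  3 replicates over 8 log-spaced concentrations (0.01–10 in the inhibitor's
  units), plus a zero-amplitude solvent control.
* **Whole-cell sessions**: each 1 Hz depolarizing pulse fuses
  Poisson(0.93) granules adding 0.1 nS each while Ca²⁺ is present
  (~28 nS over 5 min, matching the reported plateau); peak current
  G·(V−E_rev) + leak with E_rev = −62 mV and 350 pA leak at +80 mV; removing
  extracellular Cl⁻ zeroes the anionic driving-force term.
* **Puncta images**: isolated 2-D Gaussian spots (σ 200 nm on a 100 nm/px
  512² frame) placed by bounded rejection with 1.5 µm minimum separation;
  counting uses Laplacian-of-Gaussian blob detection (threshold 0.3, set so
  a blank noise field yields zero detections).

## Reproducibility and problem sizes

All randomness flows from one master seed through `SeedSequence` substreams
(per granule, channel, replicate, field); identical parameters and seed give
byte-identical arrays and tables. The shipped test suite and the acceptance
script run the full 324-granule pipeline once (≈1 min), 100-replicate Hill
recoveries, and 1000-condition GHK property sweeps — sizes chosen so the
whole suite completes in a few minutes on one CPU while keeping Monte-Carlo
standard errors well inside the asserted tolerances.

## Known limitations

* GHK machinery is monovalent-only; no activity coefficients or surface
  potentials; anomalous mole-fraction behaviour of Cl⁻/Br⁻ mixtures is out
  of scope.
* Idealization is two-level; subconductance states and hidden-Markov
  idealization are not modeled.
* The insulin-core peak of the synthetic model saturates near 106–108 nm
  (steric packing), below real-data values near 117 nm; see above.
* The EM pipeline is validated on synthetic contrast only.
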