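# Methods

`rotorsim` is a desk-scale re-implementation of the computational pipeline
used to assess the arrhythmogenic fibrotic substrate in persistent atrial
fibrillation (PsAF): simulate fibrotic atrial tissue, induce re-entrant
drivers (RDs, rotors) by programmed pacing, localize them by
phase-singularity analysis, and compare simulated driver-harboring regions
against clinically mapped ones with region-wise concordance statistics.
This note records the models, the numerical choices, and what the synthetic
substrates do and do not represent.

## Ionic models

**Detailed model.** Non-fibrotic tissue uses a human atrial
action-potential model of the Courtemanche–Ramirez–Nattel family
(21 state variables: I_Na, I_K1, I_to, I_Kur, I_Kr, I_Ks, I_CaL, pumps,
exchangers, and a two-compartment sarcoplasmic reticulum), implemented from
the published formulation with the standard constants. Chronic-AF
electrical remodeling is expressed as multiplicative conductance scalings
(I_CaL ×0.3, I_to ×0.5, I_Kur ×0.5, I_K1 ×2), and fibrosis-affected
myocytes additionally lose fast sodium and calcium current
(I_Na ×0.6, I_CaL ×0.5, I_K1 ×0.5 relative to the AF variant). These
follow the conventions of the patient-specific atrial modeling literature;
the package asserts their qualitative directions (APD shortening under AF
remodeling, upstroke slowing in fibrotic cells), never specific magnitudes,
and all scalings live in `data/variants.yaml` and are overridable.

Validated single-cell behaviour at 1 Hz: resting potential ≈ −81 mV,
maximum upstroke velocity > 200 mV/ms, APD90 ≈ 285 ms (baseline) vs
≈ 139 ms (chronic AF).

**Reduced model.** A 3-variable Fenton–Karma model is exposed behind the
same interface for tissue-scale tests where wall-clock time matters more
than ionic detail. Its parameter set is tuned so that a broken wavefront
curls into a *stable* spiral on a 5 cm sheet (fast-gate recovery
τ_v1⁻ = 1250 ms / τ_v2⁻ = 19.6 ms, τ_w⁻ = 41 ms, τ_d = 0.25 ms,
τ_0 = 12.5 ms, τ_r = 25 ms, τ_si = 29 ms, k = 10, u_c = 0.13). Two
per-node scalings parameterize fibrosis: `exc` (multiplies the fast inward
current; default 0.8 in fibrotic nodes) and `rep` (multiplies the
repolarizing current, so `rep` < 1 lengthens the action potential; default
0.7). The reduced action potential is several-fold shorter than the human
atrial one, which is why the reduced pacing protocol scales its coupling
intervals down (see below).

**Integration.** Operator-split explicit stepping: gates by the
Rush–Larsen exponential scheme, voltage and concentrations by forward
Euler. Default dt = 0.02 ms (detailed; hard cap 0.05 ms) and 0.1 ms
(reduced). APD90 changes by < 1 ms when dt is halved.

## Tissue-scale propagation

The monodomain equation C_m ∂V/∂t = ∇·(σ(x)∇V) − I_ion + I_stim is solved
on regular 2D sheets with no-flux boundaries: flux-form 5-point finite
differences for the axis terms (this conserves the spatial mean exactly in
the pure-diffusion limit), centered 9-point cross terms where the fiber
angle rotates the tensor. Explicit diffusion requires
dt ≤ h²/(4σ_max); the solver refuses to run otherwise.

**Conductivity calibration.** σ is expressed as an effective diffusivity
(cm²/s). Following the clinical calibration procedure, a global σ scale is
bisected on a 4.5 × 4.5 cm uniform-fiber slab (129×129 nodes at
h = 350 µm, within the patient-mesh edge-length range) until the
plane-wave longitudinal CV matches 43.39 cm/s, the value measured during
clinically mapped AF. The calibrated default is σ_L = 1.17861 cm²/s with
a 2:1 CV anisotropy (σ_L:σ_T = 4:1, a mid-range atrial value; only the
longitudinal target is clinically anchored). CV is measured by
least-squares regression of local activation time (LAT, first −60 mV
upward crossing) against position between the 25% and 75% lines of the
propagation axis; the fit carries a cleanliness gate (R² ≥ 0.9 by
default) that is relaxed for fibrotic media, where LAT legitimately
scatters around the mean front.

At the clinical working resolution (350 µm) the depolarization front
spans only a few nodes, so measured CV carries a systematic
discretization offset — the standard situation for whole-atria meshes,
and precisely why conductivity is calibrated *at* the working resolution
rather than taken from continuum theory. The solver's convergence
properties (CV ∝ √σ, < 3% change on halving h, CV_L/CV_T = √(σ_L/σ_T))
are therefore verified on thin fine-grid strips (h ≤ 87.5 µm), where the
front is resolved; CV being a 1D property makes those runs cheap.

**Fibrotic tissue.** Fibrotic nodes combine the fibrotic ionic variant
with scaled conductivities (longitudinal ×0.7, transverse ×0.3 for the
detailed model). With the default 29.1%-fibrosis sheet this yields a
plane-wave CV of ≈ 35 cm/s, inside the published patient-model band
[15.18, 47.81] cm/s. For the reduced model at its coarser default spacing
(500 µm) the full scaling produces *numerical* conduction block (the
reduced wavefront is a fraction of a node wide), so reduced-model runs use
milder scalings (×0.8, ×0.5); this is a numerical-resolution choice, not a
physiological one.

## Induction protocol

Programmed stimulation applies 12 stimuli with decremental coupling
intervals 300, 275, 250, 225, 200, 190, 180, 170, 160, 150, 150 ms
(total span 2,250 ms), 5 ms pulses of 0.3 mA/cm², from 1.5 mm discs at
sites on a uniform lattice (default 30 sites; seeded jitter ≤ one node).
After the train the tissue free-runs 2.5 s. The printed stimulus strength
is converted to model units through a configurable gain
(100 pA/pF per mA/cm², chosen so 0.3 mA/cm² is roughly twice diastolic
threshold for a 5 ms pulse; no conversion constants are published).

Outcomes: `no_capture` (no propagated activation), `self_terminated`
(captured but quiescent at episode end), `sustained` (any node above
−60 mV within the final 100 ms). The sustained rule is this package's
operationalization — the source analyses imply persistence to episode end
but state no explicit criterion.

The reduced-model protocol (`reduced`) uses 6 stimuli at 120, 110,
100, 95, 90 ms coupling and a 1 s free run: the same decrement-toward-
refractoriness logic, scaled to the reduced model's much shorter action
potential. Under it, homogeneous sheets never sustain re-entry, while
inducibility rises with fibrosis fraction (0 → ~50% → ~67% of sites at
fractions 0/0.15/0.30 on 5.6 cm sheets) — the monotone-vulnerability
property the test suite asserts via Spearman correlation.

## Driver detection

Phase is the temporal analytic-signal (Hilbert) angle of the
mean-subtracted voltage at each node over the final 1,000 ms of an episode
(≤ 5 ms frames), which discards the transient instability right after
induction; nodes with < 1 mV voltage excursion are flagged quiescent and
excluded. Phase singularities are plaquette topological charges: a 2×2
cell whose closed-loop wrapped phase difference sums to ±2π yields one
singularity at the cell center with that chirality. Detected points are
linked across frames by greedy nearest-neighbor matching within 3 mm/frame
(same chirality only), bridging gaps up to 2 frames. A trajectory is a
persistent RD if it lasts ≥ 200 ms *and* completes ≥ 2 rotations;
rotations are counted as the ring-averaged unwrapped phase accumulated at
16 probe points on a 2 mm circle around the trajectory centroid, divided
by 2π — robust to tip meander, exact to ±0.25 turns on analytic spirals.
Each RD is assigned to the region holding the majority of its trajectory
samples; exact ties go to the mode of the temporally later half, then to
the lowest region id.

## Synthetic substrates and the clinical observer

Patient LGE-MRI geometries are out of scope; the generator emulates their
statistical structure on 2D sheets:

- **Fibrosis**: a Gaussian random field (white noise filtered by a
  squared-exponential kernel, correlation length default 5 mm — a free
  parameter, since patch-size statistics of patient fibrosis are not
  published) thresholded at the empirical quantile, so the achieved
  fraction equals the request to one-node quantization and is monotone in
  it. Default fraction 0.291, the cohort median.
- **Regions**: a fixed 2-3-2 rectangular tiling into 7 near-equal regions
  (max/min area ratio ≤ 1.5) stands in for the 7 anatomically defined
  atrial regions; only the count and the region-wise bookkeeping matter to
  the statistics.
- **Clinical mapping observer**: region-level Bernoulli detection with
  sensitivity 20/38 ≈ 0.526 and false-positive rate 4/39 ≈ 0.103 — the
  pooled rates implied by the bundled cohort table. Maximum-likelihood
  recovery of both rates from 200 synthetic cohorts falls within their
  95% binomial CIs.

What passing tests show: the pipeline's statistics, detection and
propagation machinery behave correctly on substrates with the right
fractions, textures and detection rates. What they cannot show: anything
requiring real atrial geometry — wall thickness, endocardial bundles,
patient-specific fiber maps, or the spatial (as opposed to region-level)
co-location of simulated and mapped drivers.

## Cohort statistics

The bundled 11-patient table (per-patient counts of regions classified
`both` / `sim_only` / `firm_only` / `neither`, plus long-term ablation
outcome) drives the concordance stage. Conventions:

- **Quantiles**: `type6` (rank (n+1)p with linear interpolation) is the
  default because it reproduces the published IQRs (e.g. [1.25; 3.75],
  [0; 1.75]); Tukey fold-median hinges are also provided because one
  published variant of the success-group latent IQR ([0; 1.5]) matches
  them. Both are selectable everywhere.
- **Outcome grouping**: success = patients 1–4, failure = 5–11. The
  grouping is derived, not printed: patients are known to be ordered by
  outcome with 4 successes, and this is the only split that reproduces all
  six published per-group statistics simultaneously.
- **Tests**: exact two-sided Wilcoxon signed-rank (zero differences
  dropped, ties mid-ranked, full 2^m enumeration) and Mann–Whitney with
  0.5 tie credit (full C(n, n₁) enumeration, or tie-corrected normal
  approximation without continuity correction). Both are validated against
  brute-force and Monte-Carlo oracles in the tests.
- **Agreement**: Cohen's kappa with product marginals on the pooled
  77-region 2×2 table (0.4258 on the bundled cohort) and the
  prevalence-and-bias-adjusted variant 2p₀−1 (0.4286). The published
  "modified kappa" value (0.323) rests on an unstated formula that none of
  the standard variants reproduce on the pooled table; the module
  therefore exposes multiple named methods and asserts only the
  hand-derivable ones.

## Problem sizes used by the shipped runs

Single-cell validation paces 2–3 beats at 500–1000 ms cycle length.
Tissue runs use the 129×129 calibration slab (150–220 ms of activity),
100×100–112×112 reduced-model sheets (1.5–2 s episodes), and the
vulnerability sweep uses 21 seeded 5.6 cm substrates with two pacing sites
each. These sizes were chosen so the full suite and the acceptance script
each complete on a single CPU in well under half an hour while preserving
every qualitative regime (stable spiral, fibrosis-dependent inducibility,
clinical CV calibration) the analysis depends on.

## Known limitations

- 2D sheets with synthetic textures; no patient geometry, wall thickness,
  or transmural heterogeneity.
- The reduced model's action potential is ~4× shorter than human atrial;
  its protocol and fibrotic scalings are internally consistent but not
  quantitatively mapped to the detailed model.
- The clinical observer is region-level Bernoulli with pooled rates; it
  ignores per-patient and per-region variation in mapping quality.
- The published modified-kappa statistic is not reproducible from the
  printed data (formula unstated); see above.
- Focal (non-re-entrant) drivers are not modeled or detected, matching
  the scope of the source analysis.
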