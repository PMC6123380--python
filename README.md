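# rotorsim

Simulation and statistical analysis of the arrhythmogenic fibrotic
substrate in persistent atrial fibrillation (PsAF), at desk scale.

In fibrotic atria, re-entrant drivers (RDs, "rotors") can perpetuate
fibrillation. Clinical mapping (basket-catheter rotor mapping during an
ablation procedure) only sees the rotors that happen to manifest during
the mapped episodes; simulations on fibrosis-informed tissue models can in
principle expose every region whose substrate *could* sustain a rotor —
including **latent** driver sites that never appeared clinically and may
explain ablation failure. `rotorsim` implements that comparison pipeline
end to end for researchers in computational cardiac electrophysiology:

- **Synthetic fibrotic substrates** — Gaussian-random-field fibrosis
  textures thresholded to an exact fraction, fiber fields, a 7-region
  partition, and a stochastic region-level "clinical mapping observer".
- **Ionic models** — a human chronic-AF atrial action-potential model
  (Courtemanche-family, 21 variables) with a fibrotic-region variant, and
  a fast 3-variable Fenton–Karma model behind the same interface.
- **Monodomain solver** — C_m ∂V/∂t = ∇·(σ∇V) − I_ion + I_stim on 2D
  sheets, with conductivity calibrated so plane-wave longitudinal
  conduction velocity is 43.39 cm/s (the clinical AF mapping anchor) and
  fibrotic-sheet CV inside the published patient band [15.18, 47.81] cm/s.
- **Programmed induction** — the decremental 12-stimulus pacing train
  (300 → 150 ms coupling, 0.3 mA/cm², 5 ms pulses) at uniformly
  distributed sites, free-running 2.5 s episodes, outcome classification.
- **Rotor detection** — Hilbert-phase movies over the final 1,000 ms,
  plaquette topological-charge phase singularities, trajectory tracking,
  the ≥2-rotation / ≥200 ms persistence rule, majority-of-trajectory
  region assignment.
- **Concordance statistics** — four-category region classification
  (both / sim-only / mapped-only / neither), median [IQR] under selectable
  quantile conventions, exact Wilcoxon signed-rank and Mann–Whitney tests
  by full enumeration, and agreement kappas on the pooled 2×2 table. An
  11-patient reference cohort with ablation outcomes ships with the
  package.

## Worked example

The bundled cohort reproduces the region-wise comparison between
simulated and clinically mapped driver-harboring regions:

```python
from rotorsim.concordance import (load_cohort_fixture, summarize_cohort,
                                  wilcoxon_signed_rank, kappa,
                                  group_comparison)

fx = load_cohort_fixture()
t = summarize_cohort(fx.table)["totals"]
print(f"regions harboring simulated drivers : {t['sim']}")
print(f"regions with clinically mapped RDs  : {t['firm']}")
print(f"regions agreeing between modalities : {t['agreed']}/77")
print(f"latent driver regions (sim only)    : {t['latent']}/{t['differed']} discordant")
c = fx.table.counts()
w, p = wilcoxon_signed_rank(c["sim"], c["firm"], mode="exact")
print(f"paired Wilcoxon (sim vs mapped)     : W+={w:.0f}, p={p:.6f}")
print(f"pooled Cohen's kappa                : {kappa(fx.table, 'cohen'):.4f}")
lat = group_comparison(fx)["latent"]
for grp, label in (("failure", "failed ablation    "),
                   ("success", "successful ablation")):
    m, (q1, q3) = lat[grp]["median"], lat[grp]["iqr"]
    print(f"latent burden, {label} : {m:g} [{q1:g}; {q3:g}] per patient")
print(f"Mann-Whitney p (failure vs success) : {lat['p']:.4f}")
```

which prints (see `rotorsim compare` for the full JSON report):

```text
regions harboring simulated drivers : 38
regions with clinically mapped RDs  : 24
regions agreeing between modalities : 55/77
latent driver regions (sim only)    : 18/22 discordant
paired Wilcoxon (sim vs mapped)     : W+=28, p=0.015625
pooled Cohen's kappa                : 0.4258
latent burden, failed ablation     : 2 [2; 2] per patient
latent burden, successful ablation : 0.5 [0; 1.75] per patient
Mann-Whitney p (failure vs success) : 0.0383
```

Read: simulations flag significantly more driver-harboring regions than
clinical mapping (38 vs 24; exact paired p = 0.016), agreement is
moderate (κ = 0.43 on the pooled table), and the latent-site burden is
significantly higher in patients whose ablation later failed (median 2 vs
0.5 per patient, p = 0.038) — the observation motivating substrate-based
ablation planning.

A full in-silico run (substrate → pacing → rotor detection → observer →
statistics) with the fast reduced model:

```sh
rotorsim run-all --seed 1 --out out/demo
```

Other subcommands: `generate-substrate`, `calibrate-cv`, `induce`,
`detect-rd`, `compare` (`--help` on each).

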