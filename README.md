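# sitewater

Post-processing for molecular-dynamics trajectories of class I terpene
synthases, built for one engineering question: **can this active-site variant
still cyclize its substrate, and does it leave water in position to quench
the final carbocation?** Sesquiterpene synthases convert
(2*E*,6*E*)-farnesyl diphosphate (FDP) into hydrocarbons by deprotonating a
reactive carbocation; redirecting that cation onto trapped active-site water
instead yields complex terpene alcohols. Whether a candidate mutation is
worth building at the bench can be triaged from simulations with a handful
of geometric observables, which this package computes, aggregates across
replicas, and turns into a machine-readable report.

It is aimed at computational enzymologists who already run their own MD or
QM/MM engines: `sitewater` consumes topologies (PDB) and trajectories
(multi-model PDB, DCD, XTC, or a plain-text per-frame XYZ dialect) and does
the analysis, not the simulation.

## Metrics

For a trajectory with frames *t* = 1..*T* and an atom-role map (C1, C10,
C11, cationic C3, its three substituents, C15 protons, diphosphate (PPi)
oxygens, engineered acid atoms, water oxygens):

- **Cyclization competence** — the per-frame C1–C10 distance
  *d*₁,₁₀(*t*) (minimum-image when a periodic cell is present), its 0.1 Å
  histogram, and the extended-conformation fraction
  P(*d*₁,₁₀ > 8 Å) with a Wilson 95% CI, pooled over replicas.
  A substrate that spends much of its time extended cannot perform the
  initial C1–C10 ring closure.
- **Hydration occupancy** — the fraction of frames with exactly *k* water
  oxygens within 5.5 Å of C11 (closed ball), and per-frame close-approach
  events of water to the cationic C3 within 3.4 Å, summarised per replica
  as "k of n replicas saw an approach".
- **Water mobility** — the minimum over sliding windows (default 50 frames)
  of the rms displacement of a water from the window start; a water that
  never leaves a 1 Å pocket is operationally "stuck".
- **Prochiral face of attack** — for a trigonal-planar sp² cation the face
  normal is **n** = (s₁−c)×(s₂−c)/‖·‖ over an ordered substituent triple;
  the sign of (w−c)·**n** assigns each attacking water to the pre-*S* or
  pre-*R* face under a user-supplied `FaceConvention` (the geometric sign →
  chemical label mapping depends on substituent priorities and is never
  guessed). Hydrogen-bond partners (≤3.5 Å, D–H···A ≥ 120° when water
  hydrogens exist) are labelled PPi / acid / other and collapsed to
  coordination classes (`ppi_only`, `ppi_plus_acid`, ...).
- **Kinetics & products** — Michaelis–Menten fits
  v = V_max·S/(K_M+S) by nonlinear least squares (k_cat = V_max/E0), and
  GC peak-area normalisation to product percentages.

A synthetic-trajectory generator (`sitewater.synthetic_data`) draws each of
these observables from known distributions — a compact/extended Gaussian
mixture for *d*₁,₁₀, a categorical shell count, Bernoulli approach events
with a chosen face probability — and places atoms so the latent values are
realised exactly, giving every analysis stage a parameter-recovery test
without any MD engine.

## Worked example

Triage two synthetic "variants": a wild-type-like system (2% extended
conformations, water always in the shell) and a folding-impaired one (30%
extended conformations):

```python
import sitewater as sw
from sitewater.synthetic_data import CyclizationParams, HydrationParams

site = sw.synthetic_sitespec()
convention = sw.FaceConvention.from_site(site)
configs = {
    "WT": sw.SyntheticConfig(
        n_frames=250, n_replicas=3, seed=17,
        cyclization=CyclizationParams(p_extended=0.02),
        hydration=HydrationParams(shell_probs={1: 0.5, 2: 0.3, 3: 0.2}),
    ),
    "F297A-like": sw.SyntheticConfig(
        n_frames=250, n_replicas=3, seed=18,
        cyclization=CyclizationParams(p_extended=0.30),
    ),
}
suite = sw.make_fixture_suite(configs)
metrics = [
    sw.compute_variant_metrics(v, reps, site, sw.Thresholds(), convention)
    for v, reps in suite.items()
]
print(sw.rank_variants(metrics).to_string(index=False))
```

```
   variant  n_replicas  n_frames  cyclization_fraction   ci_low  ci_high  frac_frames_with_water  approach_k  approach_n  frac_preS  cyclization_competent  water_available
        WT           3       750              0.025333 0.016277 0.039227                   1.000           3           3   0.507042                   True             True
F297A-like           3       750              0.266667 0.236266 0.299446                   0.884           3           3   0.552301                  False             True
```

The WT-like fixture keeps 97.5% of frames below the 8 Å threshold and has
water in the 5.5 Å shell in every frame, so both triage flags pass; the
extended fixture recovers its constructed 26.7% extended fraction and is
flagged cyclization-incompetent (default threshold: ≤15% extended frames).
`frac_preS` ≈ 0.5 reflects the generator's even split of water attack
between the two prochiral faces.

Kinetics, on noiseless rates generated from K_M = 0.87 μM and
k_cat = 7.0×10⁻³ s⁻¹ at E0 = 1 μM:

```python
import numpy as np, sitewater as sw
S = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])   # μM
v = 7.0e-3 * S / (0.87 + S)
print(sw.MichaelisMenten(S, v, enzyme_conc=1.0).fit().summary())
```

```
Michaelis-Menten fit
====================
n observations     6
converged          True
K_M                0.87 +/- 6.18e-16
V_max              0.007 +/- 1.49e-18
k_cat              0.007 +/- 1.49e-18
```

The same pipelines are available from the shell via the `sitewater`
command (`synth`, `cyclization`, `hydration`, `attack`, `report`,
`kinetics`, `products`); `sitewater synth --out fixtures/` writes a
manifest that the analysis subcommands consume.

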