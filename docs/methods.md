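# Methods

This note documents the geometric definitions, statistical models and
design choices behind `sitewater`, in the order a trajectory flows through
the package.

## Coordinates, units and periodic boundaries

All coordinates and cutoffs are Ångström; XTC files (stored in nm) are
converted at read time. Atom addressing in configuration files and reports
uses PDB serials or (residue id, atom name); 0-based positional indices are
internal only, so the same site specification works across file formats.

Distances are minimum-image whenever the frame carries a cell: the
displacement is wrapped fractionally and minimised over the 27 neighbour
translates. This is exact only for distances below half the shortest cell
height, so `max_safe_cutoff` exposes that bound and cutoff-based counting
refuses cells that violate it rather than silently under-counting. Whether
analysis frames should be pre-wrapped or re-imaged around the ligand is a
caller decision; the package computes raw Euclidean distances when no box
is present and minimum-image distances when one is, and nothing else.

The selection mini-language (clauses `name/resname/resid/chain/element`
joined by `and`, multiple values OR-ed, `resid lo:hi` ranges) is
deliberately tiny: it is a config-file addressing scheme, not a query
engine. Elements missing from a PDB's element column are inferred from the
atom name (leading digits stripped, common two-letter ions recognised).

## Cyclization competence

The per-frame C1–C10 distance is histogrammed in fixed-width, half-open
bins [lo, lo+w) with w = 0.1 Å by default; the default range
[floor(min), ceil(max)] (widened by one bin if the maximum lands on the
upper edge) guarantees that counts conserve the frame total. Reports use a
fixed [3, 12] Å range for cross-variant comparability.

The extended-conformation fraction uses a strict inequality, d > 8.0 Å,
and is reported with a Wilson 95% interval. Replica sets are pooled by
frame concatenation — equivalent to a single pooled histogram — because
whether published per-variant distance histograms pool replicas or show a
representative run is often unstated; the per-replica fractions and their
across-replica standard deviation (ddof = 1) are therefore reported
alongside the pooled value, so both readings are available.

## Hydration

Water is counted by oxygen atoms of residues matching a configurable
residue-name set (default HOH/WAT/TIP3/SOL); hydrogens are ignored for
counting. The shell criterion is a closed ball (d ≤ cutoff, default
5.5 Å): "within x Å" is read inclusively. The occupancy distribution
reports the fraction of frames at every observed count, not a fixed 1–4
range. Because it is often unstated whether published occupancy counts
exclude metal-coordinated waters, the Mg-exclusion mode (drop waters
within 2.6 Å of any Mg²⁺) is off by default and, when enabled, the
excluded water identities are reported rather than silently removed.

Close approaches to the cationic carbon use d ≤ 3.4 Å and are recorded per
(frame, water) pair, so both per-frame and per-water summaries can be
derived; the per-replica boolean ("did any water ever approach?")
aggregates to k-of-n counts across replicas.

Water mobility has no standard definition, so the package uses an
operational one: the rms displacement from the window-start position,
minimised over all sliding windows (default 50 frames). The minimum — not
the maximum — is used so that a water pinned in place for any full window
scores low even if it diffuses before or after; the stuck threshold is
1.0 Å, i.e. "stuck" means never leaving a ~1 Å pocket for a window.

## Prochiral-face classification

For the trigonal-planar cationic carbon, the face normal is the normalised
cross product (s₁−c)×(s₂−c) of the first two substituents in a
user-supplied ordered triple (right-hand rule); the planarity deviation is
the centre's distance from the s₁s₂s₃ plane. A water is assigned the
convention's `positive_face_label` when (w−c)·n > 0 and the opposite label
otherwise. Classification is refused when the centre pyramidalises beyond
0.25 Å (sp² centres in QM/MM fluctuate, but a strongly pyramidalised
centre no longer has two well-defined faces) or when the approach vector
lies within 15° of the substituent plane (a grazing approach has an
ambiguous face). Both thresholds are parameters.

The mapping from the geometric sign to the chemical labels pre-S/pre-R is
deliberately *not* computed: it depends on substituent priorities
(Cahn–Ingold–Prelog) that a coordinate file does not carry. The user
asserts it once per system as a `FaceConvention`; the synthetic generator
fixes one worked convention (substituent order C2, C4, C15; +normal =
pre-S) that its construction satisfies. The classification is invariant
under rigid rotation and translation, and flips deterministically under
coordinate mirror reflection and under odd permutations of the substituent
order — these symmetries are tested.

Hydrogen bonds between an attacking water and candidate partners use
standard geometric criteria: heavy-atom distance ≤ 3.5 Å and best
D–H···A angle ≥ 120° when the topology contains the water's hydrogens;
without hydrogens the angle criterion is dropped (distance-only mode,
flagged by `angle=None` and a warning). Partner kinds come from the site
specification ("ppi" for diphosphate oxygens, "acid" for engineered
side-chain atoms — a wild-type system simply lists none), and the partner
set collapses to `ppi_only / ppi_plus_acid / acid_only / uncoordinated`.
The competing deprotonation geometry is the per-frame minimum distance
over all (PPi oxygen, C15 proton) pairs, since which proton is abstracted
is not known a priori.

## Variant triage

A variant is `cyclization_competent` when its pooled extended fraction is
≤ 0.15 and `water_available` when ≥ 0.5 of frames have at least one
in-shell water. Both fractions are this package's defaults — published
triage of this kind is typically qualitative — chosen so that a
substantially extended substrate population (a quarter or more of frames)
fails the first flag while a modest reduction in shell water does not fail
the second; both are exposed in `Thresholds` and stored in every report,
and the flags are pure functions of the stored metrics (tested by
recomputation). Ranking is total and deterministic: water-available first,
then ascending extended fraction, then variant name. Reports are written
as a flat CSV plus schema-versioned JSON with sorted keys, so regenerating
a report from the same inputs is byte-identical.

## Kinetics and product tables

The Michaelis–Menten fit is plain (unweighted) nonlinear least squares on
v = V_max·S/(K_M+S) with initial guesses K_M = median(S), V_max = max(v),
non-negativity bounds, and solver tolerances of 1e-14 with the initial
guess as the parameter scale (rates can be O(10⁻³) and the recovered
constants should be limited by the data, not the optimiser). Per-point
sigmas can be supplied for weighted fits. Fewer than three distinct
substrate concentrations is a degenerate design and raises; optimiser
non-convergence is flagged on the result, not raised. Product percentages
are proportional normalisation of peak areas, order-preserving.

## The synthetic generator

The generator emulates the *statistical structure* of the observables, not
the physics. Per frame it samples latent values and places atoms so the
latents are realised exactly, storing them in `Trajectory.metadata`:

- **Cyclization**: d(C1,C10) from a two-Gaussian mixture (defaults:
  p_extended = 0.26, compact 5.5 ± 0.7 Å, extended 9.5 ± 0.8 Å — one mode
  on each side of the 8 Å threshold, with an exceedance probability in the
  range reported for folding-impaired variants of this enzyme family),
  realised by placing C10 along a random direction from C1. The true
  exceedance probability is available in closed form from the two Gaussian
  CDFs for recovery tests.
- **Hydration**: an in-shell count k from a categorical distribution
  (default {0: .1, 1: .4, 2: .3, 3: .15, 4: .05}, matching the 1–4-water
  occupancy pattern typical of these active sites), with k waters placed
  uniformly in the [2.6 Å, cutoff] shell and the rest in a distant annulus
  beyond cutoff + 2 Å. The 2.6 Å floor excludes unphysical overlaps and
  doubles as the Mg-coordination exclusion radius.
- **Attack**: a trigonal-planar C3 with substituents at 120°, PPi oxygens
  flanking both faces, acid atoms on the pre-S side, and one attack water
  that approaches with per-frame probability `approach_rate`, on the
  +normal (pre-S) face with probability `p_preS`. Approach distances are
  N(3.0, 0.15) truncated to [2.5, 3.35] Å so that every latent approach
  falls inside the 3.4 Å detection cutoff and event counts recount
  exactly; the off-axis tilt is bounded (±0.08 in direction components) so
  an approaching water always stays within hydrogen-bond range of its
  flank's PPi oxygen. When the acid-coordination latent fires, the mobile
  acid oxygen is placed 2.8 Å from the water; otherwise it rests > 3.5 Å
  away.
- **Mobility**: each ambient water is stuck (fixed position) with
  probability `stuck_fraction`, else mobile, travelling `diffusion_step`
  Å/frame (default 0.5) at constant speed along a closed orbit of radius
  14 Å. The orbit, rather than a random walk, keeps mobile waters cleanly
  away from the stuck threshold (their window displacements have a closed
  form) and guarantees they never wander into the 3.4 Å approach shell or
  the hydration shell.

Combined "variant" trajectories place the three subsystems 60 Å apart so
no metric can cross-count another subsystem's waters. Randomness is
counter-based — one Philox stream per (seed, CRC32(variant), replica,
frame) — so replicas are independent, any frame can be regenerated in
isolation, and identical configurations are bitwise-reproducible.

What the generator does **not** emulate: force fields, water structure and
hydrogens, protein geometry beyond the named role atoms, correlated frames
(frames are i.i.d.), box vectors (synthetic frames are unboxed), or any
coupling between cyclization state and hydration. Passing recovery tests
therefore demonstrates that the *analysis* is correct and statistically
calibrated, not that any real enzyme behaves this way.

## Problem sizes and tolerances

The test suite and the acceptance script size their simulations to keep
statistical power high at desk scale: 10 replicas × 1,000 frames for
mixture-exceedance recovery (checked against the closed-form truth inside
a 99.9% binomial interval), 10,000 frames for occupancy recovery
(total-variation distance < 0.02, ~3× its expected value at that n),
≥ 2,000 approach events for face-fraction recovery and ≥ 1,000 pre-S
events for coordination recovery (99.9% binomial intervals), 200 random
triclinic cells against brute-force image enumeration (agreement to
1e-9 Å), and 100 noisy replicates for Michaelis–Menten recovery (median
K_M within 10% at 5% rate noise). The full suite runs in well under a
minute on one CPU.

## Known limitations

- No trajectory alignment/superposition, density grids, residence-time
  autocorrelation, or channel detection; solvent-exposure claims are
  summarised only through occupancy and approach metrics.
- Hydrogen-bond angles use raw (non-imaged) coordinates; for the intended
  use (a compact active site far from cell boundaries) this is exact.
- `water_mobility` compares against the window-start position, so slow
  circular motion that returns to the start within a window could in
  principle score low; the 50-frame default window makes this unlikely for
  real waters.
- The Michaelis–Menten fit assumes initial-rate data; no substrate
  inhibition or cooperativity terms are offered.
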