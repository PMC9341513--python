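# Methods

This note documents the model implemented in `chromoloop`: its physics,
its tunable parameters, the synthetic fixtures used for validation, the
numerical choices, and what the desk-scale tests do and do not show.

## The polymer model

The locus is a linear chain of beads, one bead per 1 kbp of the (possibly
rearranged) simulated genome build. Units are reduced: energies in kT
(temperature fixed at 1), lengths in σ, time in τ = σ√(m/kT) with bead
mass 1. One σ corresponds to roughly 21.8 nm of chromatin fiber, so
σ³ ≈ 1.04 × 10⁻⁵ µm³; these conversions are applied only when reporting
geometry in physical units.

The system is `n_copies` identical chains plus diffusing protein spheres,
confined in a sphere whose radius gives volume fraction `box_density` for
one reference particle volume (π/6 σ³) per particle. Sizing the sphere by
reference volume rather than per-bead volume makes the confinement track
genomic content, not fiber state: an all-open and an all-compact locus of
equal length see the same "nuclear" volume, which is what a fixed nucleus
implies. Confinement is a soft harmonic wall (20 kT/σ²). A confinement
sphere is used instead of a periodic box so that coordinates never wrap
and every observable (distances, hulls) is computed directly; at the
simulated densities the wall mimics nuclear crowding for the chain as a
whole while leaving local physics untouched.

### Force field

* **Backbone** — stiff harmonic bonds (100 kT/σ²) between consecutive
  beads, rest length the sum of the two bead radii.
* **Excluded volume** — WCA (purely repulsive Lennard-Jones, depth 1 kT)
  between all particle pairs, pair diameter the sum of radii. Pairs one or
  two apart along a chain (1-2 and 1-3 neighbours) are excluded from
  nonbonded interactions, as in standard MD practice; their geometry is
  governed by the backbone and crumpling springs. Without the 1-3
  exclusion the excluded volume would prevent the compact fiber from
  folding at all.
* **Heteromorphic fiber** — beads flagged `open_fiber` (H3K27ac-associated
  states) have diameter `open_diameter` (0.8 σ) and a cosine bending
  energy `open_persistence` (3 kT) applied where three consecutive beads
  are all open: a thin, locally stiff fiber. All other beads have diameter
  `compact_diameter` (1.1 σ) and are *crumpled* by (i) second-neighbour
  harmonic springs (`crumple_k`, 10 kT/σ²; rest length = contact) along
  compact runs, which fold the fiber back on itself, and (ii) a weak
  compact–compact attraction (`eps_compact`, 0.5 kT) acting only between
  beads of the same copy within `compact_attr_range` (20) beads of each
  other. Restricting the attraction in genomic distance is deliberate:
  crumpling is a local fiber property, and an unrestricted attraction
  makes distant compact domains coalesce into a single globule that washes
  out TAD structure. With these defaults a 100-bead open chain is
  reproducibly 3D-larger than a 100-bead compact chain (ratio of mean Rg
  ≈ 1.1–1.2), which is the mechanism behind state-driven gene-size
  changes.
* **Bridging proteins** — `n_active`/`n_het`/`n_pcg` spheres per copy
  (defaults 10/4/4, diameter 1 σ). A binding-competent protein interacts
  with beads carrying its flag (DHS / H3K9me3-state / H3K27me3-state)
  through a truncated Lennard-Jones well of depth `eps_active` etc.
  (4 kT, cutoff 1.8 × pair diameter); all other protein contacts are WCA.
  Multivalency alone then produces clustering and bridging. Proteins
  toggle binding-competence with per-step probability
  `protein_switch_rate` (2 × 10⁻⁴), a known requirement of bridging models
  to avoid permanently frozen clusters.
* **Loop extrusion** — `n_extruders` per copy (8 at desk scale). Every
  `extrude_interval` (50) dynamics steps each extruder unloads with
  probability `unload_prob` (0.01), vacant extruders load at a uniformly
  random unoccupied adjacent bead pair, and each leg attempts one outward
  step. A step is rejected if the destination bead is off the chain or
  occupied by another leg, if the new leg pair would be further apart in
  3D than `capture_radius` (4 σ), or — the CTCF gate — with probability
  `ctcf_occupancy` when the leg sits on an anchor oriented against its
  travel: "+" anchors halt right-to-left travel (left legs), "−" anchors
  halt left-to-right travel (right legs). Blocking is applied when a leg
  attempts to step *off* the anchor bead, so a trapped extruder sits with
  its legs exactly on the convergent pair; this makes "+ … −" pairs
  loop-stabilising. Leg pairs are coupled by a harmonic spring
  (`extruder_k`, 10 kT/σ²) with rest length one pair diameter. The default
  unload rate gives a mean loop residence of ~100 updates, comparable to
  the time to extrude a fixture TAD; this turnover matters — permanently
  anchored loops turn each TAD into a closed ring whose apex shows a
  spurious insulation dip.

CTCF anchor occupancies come from peak scores: either normalised to the
locus maximum (`score_normalization: max`, for real ChIP-seq scores) or
taken verbatim as probabilities in [0, 1] (`unit`, used by the synthetic
fixtures).

### Integration and protocol

Langevin dynamics with the Ornstein–Uhlenbeck velocity damping applied
exactly (v ← c₁v + c₂ξ, c₁ = e^(−γΔt)), Δt = 0.01 τ, γ = 1/τ. Initial
chains are confined random walks with overlaps permitted; a 2000-step
overdamped warm-up with per-step displacements capped at 0.1 σ anneals
overlaps away before any statistics are taken (this soft-start replaces
force capping and is unconditionally stable). Production runs discard
`equilibration_steps` (5000) and record `n_snapshots` (200) per copy every
`snapshot_interval` (250) steps, rounded to a whole number of extrusion
intervals. Non-finite coordinates abort with a diagnostic.

All randomness in one run flows from a single seed: the dynamics kernel
RNG is seeded with it directly and the extrusion/placement RNG with a
fixed derived sequence, so identical parameters give bit-identical
trajectories on the single-threaded path (the kernels are single-threaded
by construction). The pipeline driver derives per-stage seeds as
sha256(master_seed:stage_name) mod 2³¹, so stages are independently
reproducible.

### Scale

Desk-scale defaults — one copy of a few-hundred-bead locus, ~20 proteins,
snapshots spanning ~5 × 10⁴ steps — run in seconds to tens of seconds on
one core with the O(N²)-pairs numba kernel; the validation suite and the
acceptance script are sized to these defaults. Paper-scale systems (11
copies × ~3600 beads ≈ 40,000 beads in one volume, thousands of cells from
a couple of runs) are supported by the same code path but are
cluster-scale jobs; the quadratic pair loop is the known bottleneck there
and a neighbour-list kernel would be the natural extension.

## Observables

* **Contacts** — two beads are in contact when within `contact_cutoff`
  (3.5 σ). Hi-C and 4C share this cutoff by design, so a one-bead-bin
  contact-map row equals the 4C profile from that viewpoint.
* **Simulated Hi-C** — contacts pooled over all snapshots and copies,
  binned (default 10 kbp), symmetrised, reported as mean contacts per
  conformation. Iterative balancing is deliberately not applied to
  simulated maps; masking of unmappable experimental bins is propagated to
  the simulated map before any comparison.
* **Virtual 4C** — per-bin fraction of conformations in which any
  viewpoint bead contacts the bin; the viewpoint's own bins are flagged.
  Promoters are the 1 kbp immediately upstream of the TSS, strand-aware.
* **TAD calls** — diamond insulation score for windows of 3–5 bins;
  boundaries are local minima of the log₂-normalised score with prominence
  ≥ 0.4, kept when a majority of windows agree within ±1 bin. Prominence
  (rather than a depth threshold) suppresses shallow noise dips while
  keeping genuine valleys. The directionality index uses the standard
  up/downstream imbalance statistic. On an exact block-diagonal map the
  junction minimum is a two-bin plateau; the caller reports its left edge.
* **Map comparison** — Pearson correlation of directionality-index
  profiles, distance-stratified Pearson of log frequencies (strata with
  fewer than three finite pairs or zero variance are skipped), and the
  fraction of boundaries reproduced within a bin tolerance.
* **Geometry** — radius of gyration of an interval's beads, and probe
  volume as the convex hull of bead centres inflated by one bead radius
  (V + A·r + 4/3πr³, an approximation to the Minkowski sum that ignores
  edge terms; coplanar, collinear and single-bead sets fall back to the
  exact slab, capsule and sphere volumes). A hull is used rather than
  Rg³ because a FISH probe signal measures occupied volume; it remains an
  indirect measure and is treated as such.
* **Expression proxies** — `bound_fraction`: fraction of cells with an
  active, binding-competent protein within the contact radius of the
  promoter; `enhancer_contact_fraction`: fraction of cells in which the
  promoter contacts any bead whose dominant chromatin-state label is
  enhancer-associated (promoter beads excluded; an empty enhancer set is
  an error, distinguishing "never close" from "nothing to be close to").
  Fold changes between conditions are ratios of these fractions. Neither
  proxy is a linear predictor of expression; they rank conditions.

## Synthetic fixtures

The fixture generators emulate the *structure* of real inputs — convergent
CTCF anchor pairs at TAD boundaries, DHS clusters at promoters and
enhancers, contiguous chromatin-state blocks — at a few hundred kbp, with
machine-readable ground truth. They intentionally do not emulate read-level
noise, peak-strength distributions, allele-specific signal, or the long
state/anchor heterogeneity of real loci; passing the desk-scale tests
therefore demonstrates that the mechanisms work and the bookkeeping is
exact, not that real-genome predictions are quantitatively calibrated.

* **Planted-TAD locus** — `n_tads` TADs of `tad_length` beads tiling the
  locus, a convergent "+/−" occupancy-`anchor_occupancy` pair at each
  TAD's edge beads, optional DHS clusters and state blocks. With default
  engine parameters, insulation boundaries recover the planted junctions
  within ±2 of a 10-kbp bin in ≈ 90–100% of seeded runs. Extruder-driven
  loop spots can add occasional boundary-like dips inside TADs, so the
  called-TAD count can exceed the planted count; recovery is assessed as
  recall of planted junctions.
* **Rearrangement cases** — a base locus (one gene with a promoter DHS, a
  distal enhancer block, edge anchors) and an enhancer-donor segment on a
  second chromosome, composed into: identity; insertion of the donor just
  downstream of the promoter; reciprocal translocation joining the left
  arm to the reversed donor ("−" strand, exercising coordinate reflection
  and CTCF flipping); and an epigenome-swap case (identity build carrying
  the other condition's states). The base locus keeps a distal enhancer so
  that the "no insert" condition still has a non-empty enhancer-state set
  and the insertion-vs-identity contrast is a genuine near-vs-far
  comparison — the same logic as a breakpoint-position scan, for which a
  dedicated generator exists (`make_breakpoint_scan`).
* **Reference conformations** — line, ring, tetrahedron and seeded random
  walk, for closed-form observable tests.

## Numerical and design choices

* Coordinates are 0-based, half-open everywhere (BED convention); bead i
  covers [1000·i, 1000·(i+1)).
* Binding-site thresholds: DHSs mark a bead on any overlap (peaks are
  narrow); states act by ≥ 50% bead coverage (states are broad). Both are
  arguments to `annotate_beads`.
* A bead overlapped by opposite-orientation CTCF sites becomes a
  bidirectional anchor with occupancy the maximum of the two.
* Liftover drops intervals outside the build silently but *counts* drops
  and breakpoint clips in a returned report, which the pipeline logs in
  its manifest — silent interval loss is unacceptable in a rearrangement
  tool. Extruder-blocking events per anchor are likewise recorded.
* Copies in one volume interact only sterically; bridging proteins are not
  copy-assigned (they diffuse through the shared volume), which at desk
  scale (one copy) is moot and at paper scale adds a weak, physical
  coupling through the shared protein pool.
* Tie-breaks are deterministic everywhere (sorted label order for dominant
  states, slot order for extruders), so annotation and trajectories are
  reproducible byte-for-byte.
* Protein switching is applied at the extrusion cadence with the per-step
  rate compounded over the interval.

## Known limitations

* Engine parameters (binding energies, protein counts, extrusion rates,
  fiber diameters) are provisional desk-scale defaults chosen for the
  mechanisms to operate robustly at a few hundred beads; they are all
  exposed in the flat config and should be swept for any real-locus study.
* Input tracks are bulk measurements from both alleles; the model cannot
  resolve allele-specific structure.
* Simulated within-TAD structure is typically sharper than experimental
  Hi-C at matched depth; protein-mediated enhancer–promoter spots are the
  main contributors.
* The probe-volume estimator (inflated convex hull) is one of several
  defensible choices; absolute volumes depend on it, ratios between
  conditions much less so.
* Snapshots along one trajectory are autocorrelated (the chain relaxation
  time at 100 beads is comparable to the sampling window); statistics that
  matter are therefore pooled over independent seeded runs, and the tests
  do the same.
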