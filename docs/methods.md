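# Methods

This note records the models implemented by `alloscope`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results deterministic.

## Data model

Ensembles are `F × A × 3` coordinate blocks in Å with one immutable atom
record per column (author residue number, residue/atom name, backbone and
Cα flags). Author numbering is preserved end to end; contiguous 0-based
indices exist only internally (`ResidueIndexMap`). Backbone heavy atoms are
{N, CA, C, O} — the standard convention. Multi-model PDB and a plain CSV
dialect (`frame,residue,atom_name,x,y,z`) are first-class formats; DCD/XTC
go through an optional MDAnalysis adapter so desk-scale work never touches
binary codecs. Per-replica equilibration discard is exposed as a
"discard initial time" option (per method, not hard-wired globally, since
different analyses may legitimately use different spans of each replica).

## Distance fluctuation

DF_ij is the *population* variance of the Cα–Cα distance: ⟨·⟩ denotes a
plain trajectory average, so the divisor is F, not F−1. Accumulation is
streaming (Welford running mean/M2 per pair), which keeps concatenated
metatrajectories out of memory while agreeing with two-pass arithmetic to
better than 1e−12 on small fixtures; tiny negative rounding residues are
clipped at zero. No fitting or realignment is performed — internal
distances make the matrix exactly invariant under per-frame rigid motion,
which the tests assert. The per-residue flattening divides each column sum
by N (self pair contributes zero but counts in the divisor).

## Shortest path map

* **Reference frame.** Hierarchical clustering (average linkage by default,
  configurable cutoff or cluster count) on pairwise Cα RMSD after pairwise
  Kabsch superposition; the representative is the medoid of the most
  populated cluster (ties resolved to the lowest cluster label). An
  even-stride frame subsample (`max_frames`) bounds the O(F²) RMSD matrix;
  the medoid is always a genuine ensemble frame.
* **Correlation.** Frames are Kabsch-superposed on all Cα onto the
  reference before displacements are taken — displacements from a reference
  are only meaningful in a common frame. `fit=False` is available for
  fixtures generated without global motion. Residues with zero displacement
  variance get a zeroed row/column and a logged warning rather than a NaN.
* **Edge lengths.** l_ij = −ln |C_ij| with the natural logarithm; the base
  only rescales lengths and cannot change routes. Contact edges with
  C_ij = 0 are infinitely long and dropped (counted and reported).
  |C| above 1 by more than 1e−9 is an error; within tolerance it is clamped
  with a warning.
* **Paths.** One shortest path per unordered pair, via Dijkstra with
  deterministic tie-breaking: among equal-length entries into a node, the
  predecessor with the smallest internal index is kept, restricted to nodes
  settled earlier so the predecessor graph stays acyclic even across
  zero-length edges. Equal-length alternative routes are therefore resolved
  reproducibly, but any other implementation with a different tie rule can
  legitimately count ties differently — this is the one documented source
  of divergence. Unreachable pairs are counted and reported, never
  silently skipped.
* **Scores.** Edge usage normalized by the maximum (busiest edge = 1); the
  thresholded map keeps weight strictly above 0.3, and the contact criterion
  is strictly below 6 Å — both literal readings of the conventions the
  method family states. Per-residue prominence counts strictly intermediate
  visits over all pair-paths.

## Nonequilibrium response

The reactive filter is distance-only (no angle term): a frame passes iff
the nearest water oxygen is within 3.5 Å of the γ-phosphorus *and* the
lysine NZ is within 3.5 Å of the nearest γ-oxygen. 3.5 Å is the
conventional heavy-atom hydrogen-bond distance; both cutoffs are mandatory
configuration rather than hidden constants, and an optional extra predicate
slot (off by default) supports additional positioning criteria such as a
catalytic-glutamine check.

The deviation profile takes, per window and grid time, the norm of the
perturbed-minus-equilibrium Cα position difference (a "direct deviation",
not per-axis), then the mean and SEM (sample SD/√W) across windows. No
superposition is applied: perturbed windows inherit their parent's frame of
reference, and equal-time comparison cancels ordinary diffusion. SEM is
reported as undefined (NaN) for a single window rather than a misleading 0.
The conventional sampling grid — every 2 ps from 6 to 50 ps, 23 points —
is provided as `default_time_grid()`.

## Thermal-diffusion response

Per window, the endpoint frame is fitted onto the first frame on backbone
heavy atoms of residues ≤ `max_fit_residue` (default 168; the flexible
C-terminal tail above it is excluded from fit *and* output, because
including it swamps the analysis in alignment noise). The per-residue score
is the backbone RMSD between fitted endpoint and first frame, averaged over
windows. Two endpoint conventions are offered and logged —
`last_frame` (default: the state reached *by the end* of a run) and
`per_frame_mean` (trajectory-averaged RMSD) — since the phrasing used in
the field is compatible with either; neither is asserted as canonical. An
explicit `fit_residues` override supports held-fixed-fit experiments, which
is also how the tests plant an exactly recoverable 2 Å displacement.

## Consensus

Raw scores: SPM prominence, the flattened DF score, the mean Cα deviation
at one configurable snapshot time, and the mean endpoint backbone RMSD.
Each is restricted to the common residue range *first* and min–max
normalized *second* (the opposite order gives different values; a
discriminating test pins the implemented order). Min–max is the one affine
transform consistent with "scores always fall between 0 and 1" with both
endpoints attained; possible outlier clipping refinements are deliberately
not applied. A constant vector raises rather than silently filling. SPM
values are not polarity-flipped for display — the flip is metadata only, so
the row keeps its opposite chromatic trend and exports label it.

## Synthetic generator

What it emulates: (a) equilibrium Cα ensembles as Gaussian fluctuations
around a regular helical chain (3.8 Å consecutive spacing; rise 1.5 Å and
turn 100° give an α-helix-like radius ≈ 2.28 Å so i→i±2/±3 contacts exist
— a straight chain would make every contact graph a path graph), with
block-structured residue correlations acting identically and independently
on x, y, z (Kronecker with the 3×3 identity — the simplest structure that
exercises every downstream formula); (b) paired window sets carrying a
planted displacement field a·exp(−d_i/λ) with d_i measured once in the
reference frame, which keeps the planted field analytic for recovery
tests; (c) a mock active-site frame with exact requested distances.

What it does not emulate: force-field physics, solvent/membrane, realistic
secondary-structure topology, anisotropic or time-correlated fluctuations.
Passing tests therefore demonstrate that the *analyses* recover planted
statistical structure correctly, not that any real protein behaves like the
fixtures.

Default study conditions (fixed once, by analysis, as the conditions under
which the suite runs): 60-residue chain; central core block at internal
indices 20–40 with intra-block correlation 0.9, background 0.05, σ = 0.3 Å
per residue (a centrally placed rigid core flanked by looser ends mirrors
the globular-domain-plus-flexible-tail architecture the generator stands in
for); 400 frames per ensemble and 10 seeds for recovery statistics; 500
window pairs with amplitude 2.0 Å, decay length 30 Å and per-coordinate
noise 0.005 Å. The noise value is deliberately small because the deviation
statistic is a vector norm, biased upward by isotropic noise by ≈ σ²/a at
planted amplitude a; 0.005 Å keeps that bias below the 3-SEM recovery band
at the weakest planted amplitude (~0.1 Å at the far end of the chain), as
the closed-form estimate shows before any simulation is run.

## Numerical conventions and degenerate inputs

* Superposition uses the Kabsch algorithm (proper rotation guaranteed);
  fewer than 3 fit atoms or a collinear fit set is an error, not a warning.
* Dijkstra tie tolerance is 1e−12 (relative); correlation clamping
  tolerance 1e−9; PSD check floor for covariance specs −1e−8.
* Empty selections, mismatched window pairings, missing grid times,
  constant score vectors and residues missing from a method all raise typed
  exceptions naming the offender; nothing is silently filled except the
  documented B-factor fill (0.00 plus a logged warning) for unscored
  residues in PDB export.
* All sampling is driven by explicit integer seeds; identical seeds yield
  bit-identical ensembles.

## Problem sizes

The test suite and the acceptance script run the studies at the sizes
listed above (60 residues, ≤ 500 windows, ≤ 10 seeds), which this package
treats as its standard desk-scale configuration; every analysis is
streaming or O(N²) at worst, so the same code runs unchanged on
production-scale metatrajectories.

## Known limitations

* SPM tie-breaking is deterministic but convention-bound (see above);
  cross-implementation edge-usage comparisons are only meaningful on
  tie-free graphs.
* The reactive filter's cutoffs are declared defaults, not values fitted to
  any particular system.
* PDB export truncates scores to the %6.2f B-factor field; out-of-range
  scores must be rescaled by the caller (a typed error says so).
* Periodic-boundary unwrapping is out of scope; inputs are assumed
  whole-molecule.
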