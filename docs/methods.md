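# Methods

This note documents the models and procedures implemented in `confens`,
the parameters that matter and their defaults, the synthetic data the
test suite runs on, and the numerical choices made where the design was
genuinely open.

## Structures, frames and selections

A conformation is a `Frame`: an ordered list of atom records parsed from
fixed-column PDB `ATOM` lines, one frame per `MODEL` record (a file
without `MODEL` records is a single frame).  Residue numbering follows
the author numbering printed in the file — the GR DBD presets use human
numbering (lever arm 450–456, core DBD 421–491 and the 421–490
truncation used when preparing simulation systems, D-loop 457–465,
second-zinc-finger helix 469–473), and no renumbering ever happens.
Zinc `HETATM` records are parsed (the domain is a zinc-finger fold) but
excluded from every selection: all fits here are protein-Cα based.
Other heteroatoms (waters, buffer) are skipped at parse time.  Insertion
codes are unsupported and raise immediately, since silent misnumbering
is worse than a refusal.

Selections (`FragmentSpec`: residue range + atom-name filter, default
Cα) resolve deterministically: ascending chain and residue, backbone
order N/CA/C/O, then alphabetical.  Alternate locations keep the
highest-occupancy conformer, ties resolved to the lexicographically
first label.  A residue in range that lacks a requested atom raises by
default; the explicit `allow_missing` mode instead drops that residue
from **all** frames being compared, so coordinate sets stay paired.
Comparing frames whose residue sets differ without `allow_missing` is a
`TopologyError`, never a silent truncation.

## Superposition

All distances are Kabsch-fitted RMSDs: the minimum RMSD over proper
rigid motions, solved in closed form by SVD of the 3×3 cross-covariance,
with the determinant correction (sign flip of the smallest singular
vector) that forbids reflections — molecular chirality must survive a
fit.  No per-atom weighting is used anywhere.  A batched formulation
stacks the SVDs over frames, which is what makes 5·10³-frame averaging
and clustering loops cheap.

The implementation is validated against an independent brute-force
oracle (`confens.validation.euler_grid_rmsd`): for a rotation R,
N·rmsd²(R) = |P|² + |Q|² − 2 tr(R·M) with M the cross-covariance, so an
exhaustive Euler grid can be scored by one matrix product.  A 6° full
scan followed by a 1° local grid around the coarse optimum brackets the
optimum; the reported resolution bound, θ·rms_radius with θ = 1.5° (the
worst total rotation to the nearest fine node), is the slack the checks
allow.  The oracle never calls the SVD path.

The ensemble **average structure** is the standard iterative procedure:
initialize at frame 0, fit every frame to the current mean, recompute
the coordinate-wise mean, stop when the mean moves < 1e-6 Å (RMSD
between successive means) or after 50 iterations; non-convergence is
flagged on the result rather than raised.  Both tolerances are
arguments.

## RMSD series and RMSF profiles

The RMSD time series fits each frame's fragment selection to a reference
(frame 0 by default, or any coordinate set).  The RMSF profile fits
frames to the iteratively refit average **on a fit mask** and measures
fluctuations **on a measure mask**; by default the two coincide, but the
intended use fits on a stable fragment (the core domain) and measures
everywhere, so that genuinely flexible regions are not deflated by being
part of the fit.  The reference for fluctuations is the ensemble mean,
not frame 0.  For an isotropic Gaussian ensemble of per-coordinate σ the
closed form is RMSF = σ√3; fitting N atoms removes six rigid degrees of
freedom and deflates this by ≈ √(1 − 6/3N) (1.4% at N = 70), which the
5% acceptance band absorbs.

## Backbone dihedrals and angular states

Torsions follow the IUPAC convention — degrees in (−180, 180], cis = 0,
trans = 180, atan2 formulation.  φ(i) requires C(i−1); ψ(i) requires
N(i+1); missing dependencies (chain termini, gaps) mark the angle
missing with a reason, never a fabricated value.  The ideal-geometry
peptide builder places N/CA/C/O sequentially from internal coordinates
(bond lengths 1.458/1.525/1.329/1.231 Å, angles 121.7/111.0/116.6/120.8°,
ω = 180°) and round-trips through the dihedral code to numerical
precision; it is the constructive oracle for this module and the source
of backbone-bearing test ensembles.

Circular statistics use the resultant vector: mean = atan2(⟨sin⟩, ⟨cos⟩),
SD = √(−2 ln R)·180/π.  R < 1e-12 (uniform angles) has no defined mean
and raises.  Per-residue variability over an ensemble is the ordinary
interquartile range after unwrapping each angle set about its circular
median (each value shifted by ±360 into (median−180, median+180]), which
makes the spread well defined across the ±180 seam.  Quantiles are
nearest-rank (hinge-style), so the two-conformation IQR equals the
range — the natural reading for tiny crystal ensembles of eight models.

His453's backbone ψ defines the lever arm's two-state flip: presets
"out" = 143° ± 20°, "in" = −28° ± 11°, plus an optional "intermediate"
at 119° ± 13° that overlaps the out window and is therefore not part of
the default state list.  The classifier is windowed nearest-mean: a
value is labelled with the closest state whose window
(mean ± 2·SD by default) contains it, and "unassigned" otherwise, so
angles near ±90° are never forced into a state.  Transitions are counted
between consecutive distinct assigned labels; unassigned gaps are
transparent (a → unassigned → b is one a → b transition), which makes
counts reproducible and insensitive to window width at the margins.
Classifier *accuracy* is reported over the frames the classifier
actually labels, with *coverage* (fraction labelled) reported alongside:
with 2σ windows a wrapped-Gaussian emitter lands outside its own window
~4.6% of the time by construction, so folding abstentions into the error
rate would measure the window width rather than the classifier.

## Fixed-radius RMSD clustering

The clustering is the kclust-style two-phase scheme, fully pinned so
results are reproducible:

1. **Seeding** — scan frames in order; a frame joins the nearest
   existing centroid if its fitted RMSD is ≤ the cutoff radius,
   otherwise it founds a new cluster seeded at itself (centroids stay at
   their seed frames during this pass).
2. **Refinement** — recompute each centroid as the coordinate-wise mean
   of its members after fitting each member to the current centroid;
   reassign every frame to its nearest centroid with **no** radius test;
   drop emptied clusters; iterate until assignments stop changing or
   `max_iter` (default 100) is hit, in which case the model is returned
   with `converged=False`.

Clusters are reported in decreasing size order, ties broken by seeding
order.  The algorithm is deterministic given the frame order; any
shuffling is the caller's, with their seed.  The default radius is
2.3 Å on lever-arm Cα — the radius that resolves that fragment's
conformational variability in microsecond simulations of the domain —
and is an ordinary parameter; no automatic radius selection is
implemented.  Defaults follow the study design: 50,000 evenly spaced
frames for single-trajectory clustering and 5,000 per source for
combined clustering (even subsampling takes indices ⌊jL/n⌋, so frame 0
is always included).

Combined clustering pools the subsamples with source labels, clusters
once, and tabulates occupancy(s, c) = fraction of source s's frames in
cluster c (rows sum to 1).  Two sources share a cluster iff **both**
occupy it at or above the floor (default 0.10, inclusive ≥ on both
sides).

## The synthetic generator

The generator replaces microsecond MD with ensembles whose ground truth
is exact, and its defaults are the study conditions used throughout the
tests and the acceptance script:

* **Reference states.**  State 0 is a seeded pseudo-random Cα coil with
  exact 3.8 Å consecutive spacing (smoothed random step directions, so
  the trace is tangled but chain-like).  States 1..k−1 displace a
  contiguous central block (half the chain) with smooth random fields.
  The fields have the rigid-motion tangent space (translations and
  rotations about the coil) projected out, are orthonormalized, and each
  displaced state receives the same shared component,
  u_i = (w + v_i)/√2, making all k states mutually equidistant by
  construction; per-state scales are then iterated until **every**
  pairwise Kabsch-fitted RMSD is within 5% of the target (default
  6.5 Å).  The spacing guarantee applies to the coil; displaced states
  trade bond-geometry realism for exact RMSD calibration — they are
  abstract conformational stand-ins, which is all the purely geometric
  analyses under test can see.
* **Ensembles.**  A Markov chain (default: uniform switching with stay
  probability 0.95) selects the state per frame; isotropic Gaussian
  noise (default 0.2 Å per coordinate, i.e. fitted within-state spread
  ≈ 0.35 Å, comfortably inside the 2.3 Å radius) and an arbitrary
  proper rigid motion per frame are added.  True labels are returned.
* **Dihedral switcher.**  A Markov chain over angular states with
  wrapped-Gaussian emission (stay 0.99 by default, matching rapid but
  not instant two-state flipping over 10⁴ frames).  Wrapped Gaussian
  rather than von Mises because the states are specified as mean ± SD;
  at SD ≤ 20° the difference is negligible.
* **Presets.**  `conformational_selection_presets` bundles free-like
  (12 accessible states), IR-GBS-like (6) and GBS-like (2) ensembles —
  the stand-in for the observation that DNA binding and dimerization
  progressively restrict lever-arm sampling.

Everything is bit-reproducible under a fixed seed.

**What the generator does not emulate:** force-field energetics,
solvent, correlated collective motions, state lifetimes with realistic
kinetics, or bonded geometry of the displaced states.  Passing the
recovery suite therefore shows the *analysis machinery* is correct and
well-conditioned at realistic signal-to-noise, not that any particular
biological system behaves this way.

## Problem sizes

The test suite and acceptance script run deliberately scaled studies:
50 random ≤6-atom instances for the grid oracle; 70 atoms × 5,000 frames
for the RMSF closed form; 1,200–2,000 frames per trajectory for cluster
recovery (k ∈ {1, 2, 5, 12} and the three presets); 10⁴ frames for the
dihedral switcher.  These sizes give sampling errors well inside every
asserted tolerance while keeping the whole suite under a minute of
compute.

## Error handling

Exceptions are typed: configuration problems, data problems (parse
errors name the line, selection errors name the spec and residue,
topology errors name the sources) and numerical degeneracies (collinear
fits, undefined circular means) are distinct classes, mapped by the CLI
to exit codes 1, 2 and 3.  Analysis bundles are written to a staging
directory and renamed only on success, so partial outputs never persist;
every output carries a configuration hash, and bodies contain no
timestamps, so identical runs are byte-identical.

## Known limitations

* PDB only (fixed columns, `MODEL`/`ENDMDL`); no mmCIF, no insertion
  codes, no symmetry expansion.  Binary trajectory formats enter through
  the frame contract (constant topology), not a built-in reader.
* Cross-structure comparisons assume shared residue numbering; there is
  no sequence alignment, weighted fit, or outlier-rejecting trimming.
* The clustering is the pinned two-phase scheme above; it is not
  guaranteed to reproduce any particular external clustering binary
  frame-for-frame, and cluster counts from real trajectories depend on
  the seeding order (time order here).
* The seeded cluster count is empirically non-increasing in the radius
  on the ensembles tested, but the leader-style seeding pass carries no
  general monotonicity guarantee.
* B-factor conversion, covariance/DCCM analysis, Ramachandran region
  classification and side-chain χ angles are out of scope.
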