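# Methods

This note documents the models and conventions behind `gagmimic`: what each
analysis computes, the defaults and why they were chosen, what the synthetic
generators emulate, and where the genuinely open design choices were made.

## Ensembles, units, and frame selection

A conformational ensemble is a `(frames, atoms, 3)` array of coordinates in
Å with strictly increasing per-frame times in ps and an ordered atom
topology.  Units are fixed (Å, ps, kcal/mol); there are no unit options.
When a file carries no time information, frames are assumed 1 ps apart
(times 0, 1, 2, … ps), the usual save cadence of a production MD run.

Frame windows use the half-open convention `(start, end]` with the stride
anchored at the first in-window frame.  With this convention a 20 ns
trajectory saved every 1 ps contains 20000 frames, and its final 10 ns at a
10 ps stride contains exactly 1000 — the standard snapshot count for
endpoint free-energy averaging — independently of whether frame times start
at 0 or at 1 ps.  The stride must be an integer multiple of the frame
spacing; anything else is an error rather than a silent resample.

Multi-model PDB is the interchange format (MODEL/ENDMDL blocks, CONECT
honored).  Model blocks must agree in atom count and order; a disagreement
is reported with the offending model number, and unreadable coordinate
fields with their line number.  Only the first alternate location of an
atom is kept (with a warning): the source data gives no occupancy-based
rule and determinism matters more here than crystallographic nuance.  A
dense CSV (`frame,atom_index,x,y,z`) is provided for round-tripping at full
float precision, which fixed-width PDB cannot do.

Covalent bonds, needed only to identify donor hydrogens, are taken from
CONECT records when present or inferred geometrically: two atoms bond when
their distance is at most the sum of covalent radii plus 0.4 Å (the common
crystallographic slack), and a hydrogen bonds only to its nearest heavy
neighbour.

## Shape descriptors

**End-to-end distance (EED).**  The source comparisons treat EED as a
primary shape parameter but never state which atoms define the ends.  The
toolkit therefore takes a user-specified atom pair, with an automatic
default — the two heavy atoms at maximum separation in the first frame,
fixed thereafter — whose provenance (`user_specified` vs
`auto_max_extent`) is recorded in every report, so the choice is always
auditable.

**Minimum-volume enclosing ellipsoid (MVEE).**  Computed by Khachiyan's
dual-ascent iteration with Wolfe–Atwood away steps: simplex weights over
the lifted points are updated toward the point with the largest Mahalanobis
distance (or away from an over-weighted support point) until the enclosure
excess `max_i M_i/(d+1) − 1` falls below the tolerance.  Away steps give
linear convergence, so the default tolerance of 1e−6 (volumes stable to
≪ 0.1%) is reached in a few hundred iterations; the cap is 10000.
Degenerate (coplanar) inputs and non-convergence raise explicit errors.
The per-frame MVEE uses heavy atoms only by default — sulfate and ring
geometry dominate molecular shape and hydrogens merely pad the hull — but
an all-atom switch exists because the original analysis does not say which
was used.  Shape classes (spherical / prolate / oblate / scalene) use a 2%
relative axis-equality tolerance; the underlying reports are qualitative,
so the class is a label, not a statistic.  Because published "axial
lengths" are ambiguous between semi-axes and full axes, reports expose
both, and the worked-example checks accept whichever interpretation fits
better.

**Superposition and RMSD.**  Rigid superposition is the Kabsch SVD
solution restricted to proper rotations (det +1).  Pairwise RMSD matrices
use a batched formulation (one SVD per pair) so medoid searches over a few
hundred frames are instantaneous.  The RMSD-to-average series iterates
"superpose all frames to the running mean, recompute the mean" until the
mean moves < 1e−6 Å RMSD.  The test suite checks the Kabsch route against
an independent quaternion-eigendecomposition oracle.

**PCA.**  Frames are superposed to the converged mean first, so the
covariance measures conformational rather than diffusive variance; the
3N-dimensional covariance is diagonalized (via SVD of the centered data)
and frames are projected on the top components (default 3).

## Conformer clustering

The contract is a radius, not a cluster count: the smallest k (k-means on
superposed coordinates, 10 seeded restarts, k = 1, 2, …) such that every
frame lies within the radius (default 2.0 Å, the conventional conformer
granularity) of its cluster's *medoid frame* — a real conformation, chosen
as the member minimizing summed pairwise-superposed RMSD to its cluster.
Distances are always RMSD after optimal superposition, making the
clustering rigid-motion invariant.  Labels are relabeled canonically by
first occurrence, and the assignment is deterministic given the seed.  If
no k up to `max_k` satisfies the radius, the error reports the best
achieved maximum member-to-medoid distance.

## Hydrogen bonds and occupancy

Donors are N/O/S atoms with at least one bonded hydrogen; acceptors are all
N/O/S atoms (so sulfate and phenolate oxygens accept; an atom may be both).
A bond requires donor and acceptor on opposite sides of the
ligand/receptor partition, donor–acceptor distance ≤ 3.5 Å, and an angle
within the 60° cutoff.  The cutoff's angle is not defined in the source;
the default convention is *deviation of the D–H–A angle from linearity*
(∠DHA ≥ 120° at the default 60°), matching the behaviour class of the
common trajectory tools, with the alternative θ(D→H, D→A) ≤ cutoff
selectable.  The convention in force is recorded in every occupancy table.
Structures without hydrogens are refused outright — the criterion needs a
hydrogen position, and a distance-only fallback would silently change the
science.

A receptor residue is *incident* in a frame iff at least one intermolecular
bond involves any of its atoms (counted once, however many bonds it forms);
occupancy is 100 × incident frames / window frames.  Residues that never
bond are absent from the table rather than listed at 0%.  The default
analysis window is the final 50% of frames — the equilibrated half of a
production run — and the window is a required, recorded parameter wherever
occupancies are compared, because published occupancy denominators are not
always explicit.

## Energetics ingestion

Binding free energies are *ingested, never computed*: MM/PB(GB)SA totals
and single-residue decompositions arrive as CSV (`residue,mean,sd` plus a
`TOTAL` row, kcal/mol).  Dominant residues are ranked by most-negative mean
with ties broken by identifier.  The total ΔG is compared as the interval
mean ± sd.

## The three-leg verdict

The source algorithm's comparisons are visual (box plots) and verbal; to
make them operational every threshold is an explicit configurable default,
recorded in each report's provenance block:

| parameter | default | role |
|---|---|---|
| IQR overlap minimum | 0.25 | leg 1/3 shape similarity |
| \|SMD\| maximum | 2.0 | guard against offset distributions |
| docking score ratio | 0.8 | leg 2 |
| occupancy threshold | 50% | residue counts as "engaged" |
| occupancy-set Jaccard minimum | 0.25 | leg 3 occupancy similarity |
| mean-occupancy difference max | 25 points | leg 3 occupancy similarity |
| dominant-residue top-k | 3 | leg 3 energy similarity |

Distribution similarity combines the Jaccard overlap of interquartile
ranges with the pooled-sd standardized mean difference; the energy
component passes when the total-ΔG intervals overlap, with the interval
Jaccard and top-k residue Jaccard averaged into its score.  Legs are
sequential: a failure short-circuits and later legs are marked
not-evaluated; missing evidence makes a leg inconclusive rather than
failed.  The overall verdict is *mimic* only when all three legs pass,
*non-mimic* on any failure, otherwise *inconclusive*.  Ranking is by legs
passed, then mean evaluated-leg score, then label.  When several protein
targets are assessed, their reports can be combined with a user-supplied
weight vector (equal weights by default); no principled weighting is
imposed because none is established.

## Synthetic fixtures and what they do (not) show

All generators are pure functions of parameters and seed and return their
planted truth, so tests assert *recovery* rather than re-derived values:

* **Freely jointed chains** (1.5 Å links, per-frame rescaling to a
  truncated-normal end-to-end distance) emulate the unimodal EED
  distributions of flexible sulfated chains — not excluded volume, bond
  angles, or solvent structure.
* **Template mixtures with Gaussian jitter** emulate discrete conformer
  basins for clustering tests.
* **Planted-probability complexes** place an ideal donor–H–acceptor triple
  (2.9 Å, linear) or displace the acceptor to 5 Å, residue by residue and
  frame by frame, with residues 10 Å apart so bonds never cross.
* **Energy tables** plant a dominant residue a fixed gap below the rest,
  optionally noised for recovery-rate studies.

Passing tests therefore demonstrate that the *analysis layer* is correct
and self-consistent on data with known truth.  They do not demonstrate
force-field accuracy, docking quality, or MM/PB(GB)SA reliability — those
live upstream of this toolkit by design.

## Problem sizes and numerical choices

The validation suites use sizes chosen to make the statistics decisive at
desk scale: 100 random 20-point clouds for the MVEE/oracle comparison
(worst-case disagreement ~1e−11 relative), 2000-frame complexes for
occupancy recovery (99% binomial intervals a few percentage points wide),
100 seeded 40-frame mixtures for cluster-count recovery, and 20000-frame
synthetic trajectories for the subsampling contract.  MVEE tolerance 1e−6,
superposition convergence 1e−6 Å, and quartiles by linear interpolation at
position (n−1)·p with sample (n−1) standard deviations throughout.

## Known limitations

* The static worked example against the heparin NMR structure (PDB 1HPN)
  requires downloading the accession at run time; the toolkit does not
  bundle the structure.  Which six residues of the dodecamer constitute
  the hexasaccharide is not standardized, so residue-range extraction is a
  recorded user choice and the expected values carry a ±5% band.
* Only multi-model PDB and CSV are read; binary trajectory formats (DCD,
  XTC) are out of scope, as are structure building, docking, and energy
  evaluation.
* The similarity thresholds are sensible defaults, not calibrated
  constants; conclusions near a threshold deserve a sensitivity check, and
  every report records the thresholds used for exactly that reason.
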