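# Methods

This note records the models, conventions, and numerical choices behind
`structprof`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and numbering conventions

All geometry is in ångströms in a right-handed frame. Residues are
addressed by author numbering (1-based, inclusive ranges), because that is
how positions are cited in the structural literature this package serves
(e.g. a gate residue "I440"). Insertion codes are folded into an ordered
residue key. Alternate conformations are collapsed to the highest-occupancy
conformer, ties broken by altloc label order, so every downstream number is
computed on one deterministic conformer. Hydrogens are parsed but excluded
from all geometry; HETATM groups (waters, lipids, ligands) are excluded
from protein-surface computations unless explicitly included — pore runs
are protein-only by default, with a flag to include bound lipids when
studying fenestration sealing.

All area, clearance, and pocket numbers depend on the van der Waals radii
table (`geometry.VDW_RADII`, Bondi 1964 values, version `bondi64-v1`,
logged at run time). Results are only comparable between runs sharing it.

## Superposition and conformational change

`superpose` computes the least-squares rigid transform (proper rotation
only) via the Kabsch procedure (SciPy's `align_vectors`), with degenerate
(collinear, n < 3) inputs rejected. Cross-protein RMSD matrices take a
caller-supplied residue pairing (typically from an alignment); no automatic
structural aligner is included, so cross-protein RMSDs are only as good as
the pairing. The distance-difference matrix `|d_A(i,j) − d_B(i,j)|` over
shared Cα is superposition-free and rigid-invariant by construction; its
row means serve as a per-residue movement score. Note that row means are
relative: when half the residues move coherently, both halves show elevated
scores (the matrix is symmetric), so the score separates moving regions
cleanly only when they are a minority.

## Solvent-accessible surface area and interfaces

Shrake–Rupley sampling on a golden-spiral lattice (default 960 points per
atom, probe 1.4 Å). The lattice is fixed in space: identical inputs give
bit-identical areas, while rigid rotations reproduce totals only to
sampling accuracy (≈0.1 % at default density). Buried area per subunit is
SASA(subunit alone) − SASA(subunit in complex), optionally split over
caller-supplied residue ranges; the split regions must not overlap.

## Pore profiling

The published pore-profiling tools use stochastic (simulated-annealing)
searches; `structprof` replaces this with a deterministic equivalent so
tests are bit-stable. At each axial slice (step 0.25 Å) the pore centre
maximises clearance — distance to the nearest atom surface — over a fixed
25-point start lattice within a wander radius (3 Å) of the previous
centre, each start polished by Nelder–Mead. The reported radius is a true
clearance: no atom surface lies closer to the reported centre, asserted
exactly in tests. Occluded slices report radius 0 and a flag. The symmetry
axis is initialised from the plane of chain centroids and refined by
minimising the mismatch between each chain's Cα set rotated by 2π/n and
the next chain's. Membrane boundary planes come from configuration or a
hydrophobic-belt heuristic (band of aromatic+aliphatic carbon density, with
a percentile fallback for chemistry-free models). Lateral conduits are
traced by the same clearance objective marched radially from the vestibule
along directions bisecting adjacent subunits; a conduit is reported only
when it reaches bulk solvent with positive clearance throughout.

On a synthetic cylinder the profile is constant to < 0.05 Å; on the bundle
fixtures gate diameters are recovered to ±0.2 Å. Deposited-structure gate
values are checked at ±0.4 Å, reflecting sensitivity to the radii table
and sampling conventions of the original profiling program, which are not
published.

## Pocket detection

Pockets are detected on a cubic grid (0.5 Å default) aligned with the
channel axis frame. A cell is *open* when a probe sphere (1.4 Å) fits —
i.e. its centre is at least (vdW + probe) from every atom centre — and
*pocket-like* when additionally enclosed: at least 9 of 14 scan rays
(6 axial + 8 body-diagonal) hit protein volume within 12 Å. The occupied
grid is dilated by one cell for the ray test so single-cell-wide diagonal
rays do not slip through voxelisation gaps. Cells beyond the extracellular
boundary plane count as bulk solvent, never pocket. Pockets are 26-connected
components above a minimum volume (30 Å³), volume being exactly
n_cells × spacing³. Accessibility is classified by whether the pocket's
open-space component reaches the bulk solvent at the extracellular grid
face — this is what distinguishes an open sugar-binding pocket from the
occluded, membrane-facing cavity of an odorant receptor. Depth is the axial
distance from the extracellular boundary plane to the deepest cell. Lining
residues need a heavy atom within 4.5 Å of a pocket cell *and* non-zero
solvent accessibility of the isolated subunit (so the pocket interior
counts as solvent); the contact cutoff is recorded in every report.

No pocket algorithm is published for the reference analyses, so all pocket
comparisons carry wide tolerances (volumes ±30 % against literature values,
±10 % against analytic fixtures). The fixture drills are over-sized by one
atom radius plus one probe radius and snapped to the atom lattice so that
probe-erosion lands exactly on the nominal box, giving analytic truth for
volume, depth, and wall-residue sets.

## Alignment analytics

Alignments are anchored to a reference sequence whose ungapped row defines
the column ↔ residue-number map. Loop lengths between adjacent helices
count a sequence's non-gap characters in columns strictly between the
helix projections, after shrinking each helix by one residue per end to
absorb alignment noise at helix termini; zero-length loops are excluded
from summaries as likely incomplete sequences. Two residue-class schemes
coexist deliberately, matching their distinct uses: the 6-class heatmap
scheme (H aromatic) for pocket composition, and the 4-colour logo scheme
(H basic) for logos. They are never conflated.

Column frequencies are reported over all sequences by default, with the gap
fraction separate; a flag switches to the non-gap denominator. Both modes
are exercised when checking published percentages, since source
publications rarely state the denominator.

Conservation is scored per column as the Jensen–Shannon divergence between
the gap-excluded, redundancy-weighted (80 % identity clusters) column
composition and a background (default: the weighted overall alignment
composition), then binned into grades 1–9 by 9-quantiles, 9 most conserved.
This is a deliberate stand-in for empirical-Bayes rate estimation
(ConSurf-style): grade *agreement* with that method is not claimed — only
monotonicity in true conservation (Spearman ρ > 0.95 on planted gradients)
and grade 9 for invariant columns are asserted.

## Covariation

Coupling scores are mutual information over 21 states (gap included) with
sequence weights from 80 % identity clustering, pseudocount 0.5/n_eff, and
the average-product correction
score(i,j) = MI(i,j) − MI(i,·)MI(·,j)/MI(·,·). Columns with > 50 % gaps are
excluded. MI–APC replaces pseudolikelihood Potts models deliberately: it is
dependency-free and desk-scale, and the package's claims are enrichment
properties (planted-pair recovery AUPRC > 0.9; top pairs enriched for 8 Å
Cα contacts), not absolute coupled-pair counts, which are
estimator-specific and explicitly not reproduced.

## Trees and statistics

Trees are consumed as deposited (rooted as given, no re-rooting; support
values parsed but unused). A subfamily is operationally the clade under the
MRCA of named anchor taxa; published subfamily sizes are treated as
recomputable checks rather than hard targets, since a curated subfamily may
be a visually chosen superset of the strict MRCA clade.

Group comparisons use Kruskal–Wallis (tie-corrected, chi-square reference)
and the Steel–Dwass all-pairs procedure: each pair jointly mid-ranked, the
rank-sum statistic standardised with the tie-corrected variance, and
|t|·√2 referred to the Studentized-range distribution over k groups
(df → ∞). When any group has n < 5 the asymptotic reference is replaced by
a max-statistic Monte-Carlo permutation reference. The asymptotic adjusted
p deviates from the exact permutation value by up to a few percent absolute
at n ≈ 8; the permutation mode agrees with an independent oracle to
Monte-Carlo error, and the null family-wise error rate is ≤ 0.06 in 10⁴
simulated replicates.

## Synthetic study conditions

The generators' defaults encode the study conditions of the channel system
the package was built around: a C4 tetramer whose closed gate has a 2.5 Å
diameter opening to 3.2 Å, opposing gate-residue Cα distances of 9.6 Å
(closed) and 11.8 Å (open) — in the open state the Cα ring moves farther
than the lumen widens, emulating side-chain rearrangement at the gate — a
~600 Å³, ~12 Å-deep solvent-accessible pocket per subunit, a GR-family
alignment of 1,854 sequences with tyrosine at 80.7 % in the lipid-contact
column (52.9 % across 3,885 OR-family sequences), a sugar-receptor pocket
composition of 9 aromatic / 4 polar / 2 acidic / 1 basic / 5 aliphatic
dominant classes over 21 lining positions, and a 74-member fructose-receptor
subfamily clade. `scripts/acceptance.py` measures all of these back through
the full pipeline.

What the synthetic benchmarks do *not* show: the bundle is a coarse
pseudo-atom model (uniform carbon spheres, no side-chain chemistry,
perfectly symmetric), so passing tests demonstrate the correctness of the
geometry algorithms, not their robustness to real-structure noise such as
missing residues, alternate conformations, or asymmetric assemblies. The
alignment generator draws columns independently (no phylogenetic
correlation beyond the planted structure), so covariation recovery there is
easier than on real families; the redundancy-weighting path is exercised by
duplication-invariance tests rather than realistic phylogeny. Checks
against the deposited structures and alignments run whenever local copies
are present under `data/deposited/`.

## Problem sizes

Default suite sizes were chosen to keep each module's checks at a few
seconds to a couple of minutes on one CPU: bundles of ~7–10 k pseudo-atoms,
pocket grids of ~10⁵–10⁶ cells, a 10⁶-point Monte-Carlo volume oracle,
alignments of 10³ sequences × 200 columns for covariation, 10⁴ null
replicates for family-wise error, and 2×10⁴–10⁵ permutations for the rank
test oracles.
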