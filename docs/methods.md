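# Methods

This note documents the models, conventions and numerical choices behind
`metalsite`, in the order the pipeline runs.

## Structures and quality gates

Structures are read with gemmi (PDB and mmCIF); PDB header records the
parser does not surface uniformly (HEADER classification and date, COMPND
MOLECULE/EC, FORMUL formal charges) are scanned from the raw text.  Only
model 1 of multi-model files is used — the pipeline's scope is crystal
structures, and NMR ensembles would need conformer-aware featurization.
For alternate locations the highest-occupancy conformer is kept, ties
broken by altloc letter.  Header fields absent from a file stay `None`;
nothing is guessed.

Quality gates (all in `FilterConfig`): resolution strictly above 3.5 Å
drops the structure (3.5 Å exactly is kept); more than 40 metal sites
drops it (large assemblies such as virus particles); protein chains with
fewer than 20 residues are removed (peptides); nucleotide-only
macromolecules are dropped.  A missing resolution keeps the structure with
a warning by default (configurable).  Enzyme-name evidence ("…ase") is a
case-insensitive suffix test on whitespace-delimited tokens of length ≥ 5,
so "transferase" matches but "base" and "basePair" do not.  The deposited
asymmetric unit is used as-is; biological-assembly expansion is out of
scope.

## Sites and distance regions

Metal atoms of the 16 ligand codes (FE, FE2, FES, FEO, CU, CU1, CUA, MG,
ZN, MN, MO, MOO, MOS, NI, 3CO, CO) on one chain are grouped by
single-linkage clustering at 5 Å; the site center is the centroid of the
metal atoms (the natural choice for polynuclear centers, where no single
metal is privileged).  Sites with more than four metals, with another
chain's residue within 4 Å, or (when mutation annotations are supplied)
with a mutated residue within 10 Å are *flagged*, not dropped — curation
excludes them by default but the feature code can still be run on them
deliberately.

Distance regions use cutoffs 3.5/5/7.5/9 Å, as shells (annuli) or spheres
(cumulative).  Intervals are half-open `(lo, hi]`: a residue exactly at a
cutoff belongs to the inner region, which makes boundary behavior
deterministic.  Energy-term and pocket regions select residues by minimum
heavy-atom distance to the site center (the most inclusive reading);
electrostatics shells use the α-carbon distance.

## Energy-term aggregation

Per-residue score tables are inputs — this package never evaluates an
energy function.  The default schema has 21 terms; other widths are
accepted with a warning and all counts scale as 4 × n_terms.  Sums and
means are taken per region; an empty region contributes 0 for both so
downstream scaling never sees missing values.  The four aggregation
methods (mean/sum × shell/sphere) are mutually exclusive within one
feature set, enforced by the registry validator.  Because the first shell
and first sphere are the same region, their features share one identifier
(`<term>_<stat>_sphere1`), which is why four 84-feature methods yield 294
distinct names.

## Pocket detection

The cavity detector is this package's own reproducible, tool-free pocket
definition (the upstream pocket-measuring application's internals are not
published).  On a 0.5 Å grid over a 16 Å half-width box centered at the
site: cells within (Bondi vdW radius + 1.4 Å probe) of an occluding heavy
atom are occupied; the site's own metal atoms and waters do not occlude,
since otherwise the metal's exclusion sphere would hollow out the pocket
center.  An unoccupied cell is a candidate pocket cell when at least 4 of
7 scan axes (x, y, z and the four cube diagonals) are blocked by occupied
cells in both directions within 12 Å (LIGSITE-style burial).  The pocket
is the 26-connected component of candidate cells nearest the anchor
residue's closest atom — the anchor residue is the residue closest to the
site center, and "nearest candidate cell" rather than "cell containing the
anchor atom" because anchor atoms sit inside the occupied wall.  Opening
cells are pocket cells 26-adjacent to unburied space.  All thresholds
(box half-width, burial minimum, probe, scan range, grid spacing) are
`PocketConfig` fields.

Void features: volume = 0.125 Å³ × cell count; depth = Euclidean and
city-block distance from site center to the opening centroid;
centroid offset = site center to protein centroid.  For slice features the
pocket is rotated so +z runs from site center to opening center and split
into three equal-thickness z-bands (bottom/middle/top); each band is
projected to the xy-plane, giving the farthest point-pair distance, the
convex-hull area, and the second-moment ellipse of the hull vertices
(radii = 2·√eigenvalues of the vertex covariance; center offset from the
frame origin).  The moment ellipse was chosen over a minimum enclosing
ellipse for numerical stability; slices with fewer than three
non-collinear points report zero area and radii.  A fully exposed site
yields a degenerate pocket (0 cells) and the whole void category is zero,
keeping feature vectors dense.

Lining: a residue lines the pocket when a heavy atom is within 2.2 Å *of
the pocket surface*, i.e. distance to a pocket cell minus the atom's vdW
radius ≤ 2.2 Å.  Measuring from the atom center would make lining
impossible by construction — the occupancy erosion already keeps every
cell ≥ vdW + probe from every atom — so the surface-referenced distance is
the only reading under which the 2.2 Å constant is meaningful.
Sidechain-lining residues (any sidechain atom adjacent; backbone atoms of
the same residue then count with it) are separated from backbone-only
residues; glycine can only ever be backbone-only.  Hydrophobicity
statistics (mean/min/max/skew/SD; skew 0 for n < 3 or constant samples)
use the Eisenberg consensus and Kyte–Doolittle scales.  Sidechain vdW
volumes come from a bundled standard table of total residue volumes with
the glycine value subtracted as the backbone share.  The pocket is
re-detected with lining sidechains removed to get the pocket volume
without sidechains (clamped to ≥ the original volume) and the vdW volume
of that enlarged pocket occupied by the removed sidechains.  Wall surface
area is the Shrake–Rupley solvent-accessible surface area (probe 1.4 Å,
via biotite) summed over sidechain-lining residues.

## Titration electrostatics

The built-in solver is a deliberately simplified self-consistent
mean-field (Tanford–Roxby) model — not a Poisson–Boltzmann solver — with a
pluggable backend: precomputed per-residue titration tables in a simple
tabular dialect can be read instead.  Ionizable sidechains (ASP 4.0,
GLU 4.4, HIS 6.3, CYS 8.3, TYR 9.6, LYS 10.4, ARG 12.0; intrinsic pKa
table in config) interact through screened Coulomb couplings
W = 332/(ε(r)·r) kcal/mol with the distance-dependent dielectric ε(r) = 4r,
charge centers at the standard titratable sidechain atoms.  At each pH on
the 0–14 grid (step 0.05) the effective pKa of site i is
pKa_int,i − (1/(kT·ln10))·Σ_j W_ij·⟨q_j⟩ and fractions are iterated with
damping 0.5 to max|Δθ| < 1e-6 (≤ 500 iterations; non-convergence is an
error naming the pH).  An isolated residue converges in one iteration to
the exact Henderson–Hasselbalch sigmoid, and setting the interaction scale
to zero reproduces ideal sigmoids for every residue — both are regression
tests.  Strongly coupled curves can locally *rise* by up to a few 1e-4 per
pH step where a neighbor's charge state flips; this is genuine mean-field
behavior, so the monotonicity check tolerates 1e-3.  N-/C-termini are
excluded by default (config flag to include, with pKa 8.0/3.6).  The
solvation proxy is a Born-style self-energy whose effective radius grows
with burial (heavy-atom count within 8 Å); only its *ordering* is
consumed, through the quintile destabilizing/stabilizing ranks.

Per-residue scalars: central moments μ₂–μ₄ of the |dθ/dpH| density
normalized to unit trapezoid integral (moments on the derivative — the
THEMATICS convention; a config switch `moments_on` can move them to the
curve); Δ_pKa = apparent (θ = 0.5 crossing, linearly interpolated) minus
intrinsic pKa; RMS residual against the best two-parameter sigmoid
(slope bounded to [0.1, 4], initialized at the apparent pKa); quintile
rank bins (1–5) over the structure's residues by solvation energy.
Non-titrating curves (flat, or no 0.5 crossing in range) are flagged
absent and excluded from shell aggregates.  Per-site features aggregate
over the Inside (CA ≤ 3.5 Å) and Outside (3.5–9 Å) shells and apply the
environmental average x_env = Σ w·x / Σ w, w = 1/d², over ionizable
residues with d < 9 Å.  Four additional slots (environmental Δ_pKa and
residual, and the two shell counts) are computed but marked provisional in
the registry and excluded from the default training schema, because their
exact definitions could not be fixed from first principles.

## Coordination geometry

Donor atoms are non-carbon, non-hydrogen heavy atoms within 2.8 Å of a
metal (element-pair overrides in config); atoms of metal-residue-code
groups — the metal itself and its cluster partners, e.g. Fe–S sulfurs —
are excluded, water oxygens count.  The geometry library holds exactly 36
idealized geometries spanning CN 2–9, including vacant variants whose
lineage names the parent geometry missing one vertex; it is generated from
exact vertex math in code and exportable as a versioned JSON file.  The
CN-3 orthogonal tripod is shipped as a standalone geometry, not a vacancy
variant, since three missing octahedron vertices do not fit the
one-vacancy semantics.  Matching minimizes unit-vector RMSD over vertex
permutations — exhaustively for CN ≤ 6, by seeded Hungarian-assignment /
Kabsch alternation above — and the best entry decides name, vacancy and
regularity (regular ≤ 0.25, distorted ≤ 0.55 RMSD; thresholds are
unpublished upstream, these defaults make the perturbation tests
deterministic and are config-exposed).  Angular deviations are the angles
between each donor vector and its matched, optimally rotated ideal vertex.
Bond valence uses Σ exp((R0 − d)/0.37) with a bundled R0 table per
metal–donor pair (generic 1.8 Å fallback with a warning) and is normalized
by the nominal oxidation state of the metal's residue code; site charge
sums FORMUL charges of the site's metal residues (falling back to nominal
oxidation states when the file carries none).  Per-geometry one-hot
indicators are computed for reporting but excluded from the training
schema — assignments are too diverse to be useful features.

## Feature similarity

Features with fewer than 21 unique values in the dataset are discrete:
similarity is the Jaccard index of the two classes' category-proportion
vectors, Σ min / Σ max over the category union.  Continuous features use
the overlap coefficient: Gaussian KDEs (Scott's-rule bandwidth,
config-exposed) fit per class, evaluated at 2¹⁰ + 1 = 1025 points spanning
the pooled min–max, with Romberg integration of the pointwise minimum.
Zero-variance samples fall back to the discrete path with a warning;
constant features report similarity 1.

## Learning

Scaling is the robust quantile scaler x' = (x − median)/(q80 − q20)
(constant features are centered only); under-sampling keeps all positives
and draws ⌊3·n_pos⌋ negatives without replacement, seeded.  Nested CV:
the table is under-sampled once, then within each outer stratified 7-fold
split an inner grid search over stratified shuffle splits (5 splits, 20 %
validation — the inner-loop geometry is an assumption, documented here)
picks hyperparameters per scorer (accuracy, precision, MCC, or the
multi-score — the unweighted mean of accuracy, MCC and Jaccard,
config-exposed).  The scaler is fit inside each outer fold on the training
part only, so test-fold statistics never leak into it.  The most
frequently selected hyperparameter set is then re-evaluated over the outer
folds of the full table, ten repetitions per fold with fresh seeds for the
algorithm and for re-under-sampling the training fold (70 evaluations),
and models with accuracy SD > 6.5 %, TNR SD > 9 % or MCC SD > 0.11 across
those evaluations are marked unstable.  The final predictor trains ten
members on ten fresh under-samples; the mean member vote is the score and
≥ 0.5 calls the site enzymatic.  MCC with any zero denominator factor is
defined as 0, so constant-class predictors score 0.  Impurity importances
are normalized to max = 100 per member and averaged.  The algorithm roster
(extra trees, random forest, gradient boosting, logistic regression, SVM)
covers the method families that matter; wider sweeps are configuration.

## Curation

Labeling is pure logic over adapter-supplied evidence tables — homology
hits (E-values), structural alignments (TM-scores with catalytic-residue
coordinates mapped into the query frame), and name evidence — because the
external search/alignment tools and database snapshots are not
reproducible inside tests.  Gates: hit E ≤ 1e-6, name evidence (EC or
"ase"), TM ≥ 0.40, catalytic residue within 5 Å → enzymatic; remaining
sites on enzymatic chains → non-enzymatic; no evidence at all →
non-enzymatic; anything partial → discarded with reason codes.  Local site
similarity is the Jaccard index over residue-identity *multisets*
(duplicates counted) within 3.75 Å (within clusters) or 6.0 Å (across
sets), excluding the metal residues themselves; pairs strictly above 0.80
are redundant and resolved by the keep priority (catalytic, ligand-free,
isolated, mutation-free, resolution; lexicographic tie-break).  Special
filters remove non-enzymatic Mg sites within 10 Å of a nucleic-acid
phosphate and sites whose metal moved more than 3 Å between supplied
coordinate sets.

## Synthetic fixtures: what they do and do not show

The fixture generators produce geometrically exact toy systems — a
tetrahedral Cys₂His₂ zinc site in a domed cavity, a surface magnesium with
no pocket, a dinuclear zinc pair at 4.9 Å, a hemispherical cavity of known
analytic volume, and Gaussian feature tables with controlled effect sizes
at a realistic 24 % positive class balance.  They exercise every code path
deterministically (same spec + seed → byte-identical files) and serve as
oracles: the cavity walls are built on the boundary of the intended void
dilated by the occupancy erosion distance, so the detected volume is
analytically predictable, and the sealed-ceiling variant makes the void
exactly a hemisphere (the metal sits half a grid cell below the mouth
plane so no voxel layer lies on the flat boundary).  What passing these
tests does *not* show: performance on real crystal structures, with their
partial occupancy, alternate conformations, waters, and genuinely
ambiguous chemistry — the published headline classification metrics
require thousands of curated PDB structures and externally computed
energy tables, which are outside this package's desk scale.

## Known limitations

* The electrostatics solver is a fast stand-in with a crude dielectric and
  solvation model; absolute pKa shifts are not quantitative, and only the
  curve-shape statistics and rankings it feeds are consumed downstream.
* Pocket detection thresholds (burial ≥ 4 of 7 axes, 12 Å scan) are a
  reproducible re-specification, not a reimplementation of the upstream
  tool; absolute volumes are comparable only within this definition.
* The geometry library's vertex sets are idealized references; regularity
  thresholds are package defaults, not published constants.
* Homology and alignment evidence is consumed, never computed; label
  quality is bounded by the supplied evidence tables.
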