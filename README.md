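# metalsite

Structure-based featurization and enzymatic/non-enzymatic classification of
protein metal-binding sites.

About 40 % of enzymes are metalloenzymes, and their active sites are
physicochemically very similar to inactive metal-binding sites — the same
charged and polar residues coordinate the metal in both.  Telling a
catalytic zinc from a structural or adventitious one is therefore hard, and
matters both for annotating native structures and for vetting designed
enzymes.  `metalsite` is a toolkit for researchers working on that problem:
it locates metal sites in crystal structures, computes five families of
physicochemical features around each site, quantifies how similar each
feature's distribution is between the enzymatic and non-enzymatic classes,
and trains/applies a decision-tree-ensemble classifier that labels each
site enzymatic or non-enzymatic.

## What it computes

A **site** is the set of metal atoms (Fe/Cu/Zn/Mn/Mg/Mo/Ni/Co ligand codes)
bound to one protein chain, merged by single linkage at 5 Å; the site
center is the metal centroid.  Around each site:

1. **Energy-term aggregates** (`ros_`) — per-residue score-table terms
   (21-term tables are inputs) summed or averaged over concentric shells
   (0–3.5, 3.5–5, 5–7.5, 7.5–9 Å) or cumulative spheres.  Each of the four
   aggregation methods yields 21 × 4 = 84 features; the union has 294
   distinct identifiers because the first shell equals the first sphere.
2. **Pocket void geometry** (`pok_`) — a LIGSITE-style burial-scanned
   cavity on a 0.5 Å grid: volume (0.125 Å³ per cell), depth and city-block
   distance from site center to pocket opening, distance to the protein
   centroid, and per-slice shape metrics (farthest point pair, convex-hull
   area, moment-ellipse radii) for three z-bands of the rotated pocket.
3. **Pocket lining** (`lin_`) — residues adjacent to the pocket, split
   into backbone-only and sidechain groups; hydrophobicity statistics
   (Eisenberg and Kyte–Doolittle), lining counts, sidechain van der Waals
   volumes, pocket volume without sidechains, and wall solvent-accessible
   surface area.
4. **Electrostatics** (`ele_`) — theoretical titration curves θ(pH) for
   ionizable residues from a mean-field (Tanford–Roxby) solver with
   screened-Coulomb couplings W = 332/(4 r²) kcal/mol and ε(r) = 4r.
   Per-residue scalars follow the THEMATICS tradition: central moments
   μ₂–μ₄ of the normalized |dθ/dpH| density, apparent-vs-intrinsic pKa
   shift, RMS deviation from the best-fit sigmoid, and quintile solvation
   ranks; per-site features aggregate them over two α-carbon shells
   (Inside ≤ 3.5 Å, Outside 3.5–9 Å) and as inverse-square-distance
   environmental averages  x_env = Σ w·x / Σ w with w = 1/d².
5. **Coordination geometry** (`geo_`) — the coordination polyhedron matched
   against 36 idealized geometries (CN 2–9, with vacant variants) by
   permutation + Kabsch RMSD; donor counts by element, angular deviations,
   formal site charge from FORMUL records, and the bond valence sum
   Σ exp((R0 − d)/0.37) with its oxidation-state-normalized value.

Feature-class **similarity** uses the Jaccard index of category proportions
(Σ min / Σ max) for discrete features (< 21 unique values) and the overlap
coefficient — Romberg-integrated area under the minimum of the two
Gaussian KDEs on a 1025-point grid — for continuous ones.

**Learning** mirrors the imbalanced-site protocol: robust quantile scaling
(20th/80th), random 3:1 under-sampling of non-enzymatic sites, nested CV
(grid search in stratified shuffle splits inside a stratified 7-fold outer
loop), a stability filter on fold SDs (accuracy ≤ 6.5 %, TNR ≤ 9 %,
MCC ≤ 0.11), and a final ten-member ensemble whose mean vote ≥ 0.5 calls a
site enzymatic.  The headline metric is the Matthews correlation
coefficient, MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

## Worked example

Everything is runnable on bundled synthetic fixtures — no downloads:

```bash
metalsite fixtures --scenario zinc_tetrahedral_pocket --seed 7 --out-dir demo
metalsite extract-sites demo/zinc_tetrahedral_pocket_7.pdb -o demo/sites.tsv
metalsite featurize demo/zinc_tetrahedral_pocket_7.pdb \
    --energy-table demo/zinc_tetrahedral_pocket_7_energy.tsv \
    -o demo/features.tsv
```

prints

```
wrote demo/zinc_tetrahedral_pocket_7.pdb and demo/zinc_tetrahedral_pocket_7_energy.tsv
wrote 1 sites to demo/sites.tsv
wrote 1 sites x 171 features to demo/features.tsv
```

The fixture is a zinc ion coordinated by two cysteine sulfurs and two
histidine nitrogens at 2.1 Å in perfect tetrahedral directions inside a
domed cavity.  The site table reports one ZN site centered at the origin;
the feature table carries all five category prefixes.  Because the
construction is geometrically exact, the features are predictable from
first principles, e.g.:

```python
>>> from metalsite import read_structure, find_sites, coord_features
>>> s = read_structure("demo/zinc_tetrahedral_pocket_7.pdb")
>>> site = find_sites(s)[0]
>>> cf = coord_features(site, s)
>>> cf.matches[0].name, round(cf.matches[0].rmsd, 6)
('tetrahedron', 0.0)
>>> cf.features["geo_n_n_total"], cf.features["geo_n_s_total"]
(2.0, 2.0)
>>> cf.features["geo_site_charge"]      # FORMUL: ZN 2+
2.0
```

Training and prediction run on labeled feature tables
(`metalsite train`, `metalsite predict`); `metalsite similarity` produces
the per-feature class-similarity report, and `metalsite curate` applies the
homology-evidence labeling rules to an assembled evidence file.

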