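# Methods

## Model

`hatslens` computes the H-GETAWAY leverage-weighted autocorrelation
descriptors HATS(k, w) of an explicit-hydrogen 3D structure, keeping every
summand so the value can be attributed to atomic pairs and molecular
fragments.

The pipeline has three independent ingredients:

1. **Topology.** The molecular graph (atoms = vertices, bonds = edges) gives
   topological distances `d_ij` — bond counts on shortest paths, computed by
   breadth-first search (SciPy `csgraph`). The Dirac delta
   `delta(k; d_ij)` selects the unordered pairs at lag `k`. Distances are
   purely graph-theoretic, never Euclidean. Disconnected pairs (salts,
   multi-fragment inputs) carry an infinite sentinel and never match a finite
   lag, which is exactly the behavior the delta implies.

2. **Geometry.** Coordinates are centered on the unweighted geometric center
   (no mass weighting — all atoms count equally). The molecular influence
   matrix `H = M (M^T M)^-1 M^T` is the orthogonal projector onto the column
   space of the centered coordinate matrix `M`; its diagonal entries are the
   leverages. Projector identities give the invariants the code enforces and
   the tests check: `0 <= h_ii <= 1`, `trace H = rank M = D`, mean leverage
   `D/A`, idempotence, off-diagonal entries in [-1, 1], and invariance under
   rigid motion.

3. **Weights.** Per-element physicochemical properties divided by the carbon
   value, so `w(C) = 1`: unweighted (u), IUPAC atomic masses (m), van der
   Waals volumes from Bondi radii (v), Sanderson electronegativities (e), CRC
   polarizabilities (p) and first ionization energies (i). Raw tables ship as
   a commented CSV resource covering H, B, C, N, O, F, Si, P, S, Cl, Br, I.
   The electronegativity scale is a convention choice; Sanderson is used
   because it is the scale of the Dragon-style descriptor systems this
   implementation is compatible with. Values computed with a different scale
   will differ slightly for scheme `e` only.

HATS0 sums squared self terms `(w_i h_ii)^2`; HATSk for `k >= 1` sums
`(w_i h_ii)(w_j h_jj)` over the lag-k pairs. Batch profiles default to
lags 0–8, the customary autocorrelation range.

## Numerical choices

* **SVD projector, not the literal inverse.** `M^T M` is singular for exactly
  planar (D = 2) or collinear (D = 1) molecules — including reference
  structures used here (hexabenzocoronene, benzene). The projector is built
  from the singular vectors with singular values above `1e-8` (relative);
  the explicit inverse is the full-rank special case. An all-zero `M`
  (single atom) yields D = 0 and H = 0, documented rather than an error.
  Symmetry of H is enforced by averaging with its transpose, and leverages
  are clipped to [0, 1] against last-ulp round-off.
* **Deterministic orderings.** Pair lists are sorted by descending
  contribution with (i, j) tie-break, so "how many pairs cover 80% of the
  value" is reproducible across platforms. Coverage comparisons use a `1e-9`
  relative slack to absorb floating-point summation error when many exactly
  equal contributions are accumulated (e.g. 300 identical pairs in C60).
* **Bond perception** (needed for XYZ input and fixture validation) bonds two
  atoms when their distance is at most `scale * (r_i + r_j)` with Cordero
  single-bond covalent radii and `scale = 1.15` (a common heuristic,
  overridable).
* **Indexing.** Atom indices are 1-based in every user-visible artifact
  (pair reports, fragment files, bond lists), the SDF convention.

## Interpretation machinery

* **Fragment decomposition** routes each pair contribution to the unordered
  cell (frag(i), frag(j)) of a user-supplied total partition; HATS0 self
  terms are intra-fragment by construction. Cells sum to the descriptor
  exactly (same summands, regrouped), which the tests assert against an
  independent re-binning loop.
* **Substructure cutting** deletes atoms and keeps original coordinates of
  the survivors — no hydrogen capping, no re-optimization, preserving the
  spatial arrangement of the surviving pairs. Everything is recomputed on the
  cut structure: leverages are global geometry scores, so they are never
  sliced from the parent. Cutting shrinks A while the coordinate rank stays 3
  (generically), so the mean leverage `D/A` rises — the size effect the
  cutting analysis is designed to expose.
* **Conformer shape clustering** compares conformers (same element sequence
  and bond set, hence the same lag-k pair basis) through their raw
  pair-contribution vectors, by Euclidean distance, under UPGMA (SciPy
  average linkage). Raw (unnormalized) contributions are the default because
  the analysis clusters contributions directly; `normalize=True` switches to
  unit-sum vectors when only shape, not magnitude, should matter. The
  cophenetic correlation coefficient (Pearson correlation between input and
  tree-implied distances) summarizes dendrogram faithfulness; it is exactly 1
  on ultrametric inputs and undefined (raised as an error) for two leaves or
  zero-variance distances. Fingerprints use all lag-k pairs, not only the
  top-coverage subset.

## Reference structures and the synthetic conformer generator

All test structures are generated, never downloaded:

* **Fullerene C60** — truncated icosahedron with 6:6 bonds 1.40 Å and 6:5
  bonds 1.46 Å (icosahedron edges truncated at the fraction that yields both
  lengths). Icosahedral symmetry makes all 60 leverages equal, pinning
  HATS5m at `300 * (3/60)^2 = 0.75` independent of the radius.
* **n-alkanes** — all-anti zigzag chains, C–C 1.54 Å, C–H 1.09 Å, exact
  tetrahedral angles; CnH2n+2 with terminal CH3 and interior CH2 hydrogens
  placed from local bond directions.
* **Hexabenzocoronene C42H18** — 13 fused ideal hexagons (C–C 1.42 Å) with 18
  peripheral hydrogens, strictly planar (z = 0), chosen as the honeycomb
  sheet fragment with that formula. Topological targets (pair counts) are
  bond-length independent.
* **Halide probe** — a para-methyl benzene scaffold whose probe site (H, F,
  Cl or Br) is frozen at 1.74 Å from the ring for every element, so the
  leverage set is identical across the series and descriptor differences
  isolate the atomic weight. The probe's single lag-5 partner of X is the
  methyl *carbon*: with a hydrogen partner the unweighted product can exceed
  the mass-weighted one (w_m(H) ≈ 0.084 outweighs w_m(Br) ≈ 6.65 in the
  product), so a carbon partner is the configuration in which mass weighting
  demonstrably amplifies halogen contributions. Because the X–C distance is
  frozen chemically unrealistically for X = H/F, the probe sets its bond list
  explicitly instead of relying on distance-based perception.
* **Synthetic conformers** — one alkane-chain topology (default C12) with
  backbone dihedrals set per shape class: all-anti (linear), one gauche kink
  pair at mid-chain (L), two kink pairs at the 1/4 and 3/4 positions (U),
  plus seeded Gaussian coordinate jitter (σ = 0.02 Å). The generator is the
  study condition for the shape-clustering stage: three geometrically
  distinct, well-separated classes with within-class jitter. It emulates the
  *shape variability* of a conformer ensemble, not its energetics: real
  force-field ensembles have correlated torsion changes, uneven class sizes
  and borderline geometries, so perfect 3-cluster recovery here shows the
  fingerprint/UPGMA machinery separates planted shape classes — not that any
  real ensemble clusters this cleanly (real cophenetic correlations will be
  materially below the ≈0.999 of the synthetic sets).

## Problem sizes

Tests and the acceptance script run on the reference structures (≤ 62 atoms),
random connected molecules of ≤ 30 atoms for oracle-equivalence and invariant
suites (50–100 replicates), and conformer sets of 6–18 chains; the whole
suite completes in seconds.

## Design notes

* The functional core follows the pipeline stages (I/O, topology, influence
  matrix, weights, descriptors, decomposition, clustering); the two
  transform-shaped stages are additionally exposed as scikit-learn estimators
  (`HATSFeaturizer`, `ConformerShapeClusterer`) for pipeline composition.
* Input geometries are taken as given — no geometry optimization anywhere, so
  results are exactly reproducible from coordinates.
* Structures with more than one heavy atom and no hydrogens trigger a warning
  (HATS descriptors are defined on explicit-hydrogen structures) but compute
  fine; the math does not require hydrogens.
* Bond orders, aromaticity, charges and stereochemistry are ignored: none
  enter the descriptor definition.

## Known limitations

* R-GETAWAY descriptors (influence/distance matrix based) and other
  H-GETAWAY indices (ITH, ISH, HIC, ...) are out of scope.
* Weight tables cover 12 common organic elements; others raise a clear error
  rather than falling back to a default.
* The conformer clustering quality metrics are only as meaningful as the
  input ensemble; the package does not generate conformers for real
  molecules.
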