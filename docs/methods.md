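# Methods

This document describes the functional forms and algorithms implemented
by `molsample`. Units are kcal/mol for energies, Å for distances, and
elementary charges for partial charges throughout.

## 1. Molecular model (`molsample.chem`)

A `Molecule` is a list of typed atoms (GAFF-style force-field types,
partial charges, optional residue metadata and a `fixed` flag), a bond
list with integer orders, and an `(n, 3)` coordinate array. From the
topology we derive:

- **Interaction roles.** Each atom is classified as `donor_H` (polar
  hydrogens: `hn`, `ho`, `hw`, …), `acceptor` (carbonyl/hydroxyl/ether
  oxygens, most nitrogens, …), `hydrophobe` (carbons, subdivided into
  *polarized*, *aromatic* and *aliphatic* classes), or `none`.
- **Symmetry sets.** Topologically equivalent atoms are grouped by a
  Morgan-style refinement seeded on (element, charge bucket) and
  iterated over neighbor classes, bond orders and the multiset of
  topological distances. Equivalent atoms may belong to different
  connected components (the two oxygens of a carboxylate form one set;
  so do the carbons of two separate methanes).
- **Rotatable bonds and fragments.** Single, acyclic, non-terminal
  bonds are rotatable; ring bonds can be *declared broken*, which makes
  them rotatable and defines ring-opening fragments. Fragments are
  either *bound* (still attached through at least one rotatable bond)
  or *loose* (a separate connected component, e.g. a ligand).

## 2. Force field (`molsample.forcefield`)

The intramolecular part is a standard Class-I expansion: harmonic bonds
and angles, cosine torsion series read from AMBER `frcmod`-format
tables, and 6–12 van der Waals plus Coulomb terms for topologically
separated pairs (vicinal 1–4 pairs are scaled by the scheme's
`vicinal_weight`). All pair terms are evaluated on squared distances
shifted by a small offset `d2offset = 0.01 Å²`, which keeps energies
and gradients finite at overlap and makes every term smooth.

Additional terms:

- **Coulomb.** `E = 332 q_i q_j / (ε d²)` with the distance-dependent
  dielectric folded into the squared distance; `ε` is per scheme.
- **Desolvation.** A charge-burial penalty applied to pairs whose
  charge product exceeds `minq_to_desolv`, proportional to
  `desolv_factor · |q_i q_j| / d²`, scaled down by `desolv_scale_ion`
  (salt bridges) or `desolv_scale_hb` (hydrogen-bonded pairs) in the
  fitted scheme. A matching `hbond_bonus` rewards donor–acceptor
  contacts.
- **Hydrophobic contact bonus.** For hydrophobe–hydrophobe pairs a
  smooth cosine switch `s(d²)` falls from 1 to 0 over 4.5–5.5 Å; the
  bonus is `−K_a K_b^{1/2}`-style per-class constants (`K_polarized`,
  `K_arom`, `K_aliph`) times the switch.
- **Termination.** Every pair's energy is multiplied by a smooth weight
  `ω(d)` that reaches exactly zero at a per-pair cutoff found by
  scanning the pair's own energy profile (capped at 15 Å); beyond the
  cutoff the pair contributes nothing and the energy stays continuous
  and differentiable.
- **Chirality and out-of-plane.** Tetrahedral stereocenters carry a
  signed-projection reference `p₀`; a flip of sign costs
  `k_chir · |p|` (k = 100). Trigonal centers (amide N, carbonyl C) pay
  `k_oop · (|p| − 0.01)` beyond a 0.01 Å pyramidalization threshold
  (k = 200).
- **Torsion restraints.** Harmonic `k (φ − φ₀)²` restraints can be
  attached and removed at runtime; driven mutation uses them
  transiently.

Pairs in which both atoms are fixed (receptor–receptor) are excluded at
model build time, so a rigid site contributes no internal energy.
Analytic gradients are implemented for every term and match central
finite differences to better than 1 part in 10⁵; fixed atoms always
receive zero gradient.

### Parameter schemes

Three named schemes reproduce the published parameterization stages:

| constant | core | preliminary | fit |
| --- | --- | --- | --- |
| epsilon | 2.0 | 4.0 | 4.0 |
| desolv_factor | 0 | 0.1 | 0.1 |
| minq_to_desolv | 0 | 0.125 | 0.125 |
| hbond_bonus | 0 | 2.0 | 2.0 |
| repulsive_factor | 1.00 | 0.75 | 0.75 |
| vicinal_weight | 0.5 | 0.033 | 0.033 |
| desolv_scale_ion | 1.0 | 1.0 | 0.1 |
| desolv_scale_hb | 1.0 | 1.0 | 0.1 |
| K_polarized | 0 | 0.1 | 0.01 |
| K_arom | 0 | 0.1 | 0.15 |
| K_aliph | 0 | 0.1 | 0.15 |

The hydrophobic triplet `(K_polarized, K_arom, K_aliph)` can be
re-fitted by a 10×10×10 grid scan (`scan_triplets`) over the printed
K values {0, 0.010, 0.025, 0.050, 0.075, 0.100, 0.150, 0.200, 0.250,
0.300}. Because the contact term is affine in the three constants, each
pose's energy under any triplet is `E₀ + s · k`, with a per-pose
3-vector `s` precomputed once (`prepare_scan_complex`); the full
1000-point scan over many complexes costs seconds. Ties are broken by
snapping to the component-wise median of the winning triplets.

## 3. Pairwise interaction fingerprints (`molsample.fingerprints`)

A fingerprint feature is an eligible ordered pair of symmetry sets:
hydrophobe×hydrophobe or donor–acceptor, at topological separation
> 5 bonds (disjoint components count as separated), with at least one
free atom. Its value is the self-weighted average of the member-pair
contact switches,

&nbsp;&nbsp;`PIF_k = Σ C_ij² / Σ C_ij`,

which is biased toward the strongest contact, bounded by the member
extrema, and — crucially — invariant under any permutation of
equivalent atoms: a 180° carboxylate flip changes individual distances
but not the fingerprint. The distance between two fingerprints is the
mean absolute per-feature difference (`pif_distance`), a metric on
[0, 1].

A member's **originality** ω is its minimum fingerprint distance to any
*strictly fitter* population member; the fittest member, a member of a
singleton population, and any member of a system with an empty layout
get a sentinel maximum (the diversity machinery is inert when the
fingerprint carries no evidence).

**Symmetry-aware RMSD** minimizes the plain (no-superposition) RMSD
over permutations of equivalent heavy atoms, solved per symmetry set by
linear assignment; a brute-force permutation enumeration (≤ 10⁴
permutations) is available as an oracle and agrees exactly.

## 4. Operators (`molsample.operators`)

- **Local optimization** (`local_opt`): conjugate gradients with Armijo
  backtracking on free atoms, returning the best visited point;
  `exhaustive_minimize` alternates L-BFGS-B cycles on the nominal and a
  bond-softened surface to escape bad local contacts.
- **random_init**: randomizes all rotatable torsions and, for loose
  fragments, draws a contact axis between a random fragment atom and a
  site hot spot, places the fragment on that axis at van der Waals
  contact (`place_on_axis`, probe radius 1.1 Å), resolves clashes by
  translation/rotation trials (`dock_c`), and optionally polishes with
  a patience-limited stochastic descent (`dock_e`).
- **Crossover** (`cross`): with the fragment-recombination probability,
  a random fragment of parent 1 is rebuilt in the geometry of parent 2
  — by torsion transfer across the connecting bond for bound fragments,
  or by re-docking for loose fragments; otherwise (or on failure) a
  uniform torsional crossover mixes per-bond torsions from both
  parents.
- **Mutation** (`mutate`): a random fragment is re-initialized, or a
  *driven* torsion mutation applies a transient harmonic restraint to a
  random torsion target, relaxes, and removes the restraint. Systems
  with no fragments fall back to single-torsion jumps.

All operators draw exclusively from an explicit `numpy` Generator, and
chirality restraints keep stereocenters intact through arbitrary
operator sequences.

## 5. Evolution (`molsample.evolution`)

Three strategies share one configuration (`EvolutionConfig`):

- **evol** — steady-state: each generation performs population-size
  crossover/mutation trials; offspring enter by *fitness replacement*
  (`might_replace`: an offspring better than the worst of its parents
  replaces the least-fit parent) or by *diversity replacement*
  (`replace_most_redundant`: the least-fit member among those with
  ω ≤ 1.1 ω_min is replaced if the energy excess is at most
  `div2e · Δω`). A per-generation sweep (`randomize_if_redundant`)
  re-randomizes redundant members (trigger probability `1 − ω/minfpdiff`)
  when a candidate satisfies `E(M) − E(I) < div2e · (ω(M) − ω(I))`.
- **sga** — generational with tournament selection.
- **ega** — generational with an elite fraction (default 20 %) carried
  over unchanged, so the best energy is non-increasing.

Every evaluated individual feeds an **archive** deduplicated on
(rounded energy, rounded fingerprint) and returned energy-sorted. Runs
are bit-reproducible from `(config, seed)`.

## 6. Docking pipeline (`molsample.pipeline`)

`prepare_site` cuts a site from a protein by keeping every residue with
any atom within the radius of the reference ligand (waters removed,
cofactors kept), fixes all site atoms, and records the heavy-atom
center. `auto_hot_spots` selects role-bearing site atoms within 6 Å of
the center. `assemble_complex` concatenates site and ligand.
`filter_poses` drops poses whose ligand centroid strays more than 8 Å
from the site center or whose energy exceeds the best by 30 kcal/mol,
optionally refines the survivors exhaustively, and keeps at most 30
mutually non-redundant poses (pairwise fingerprint distance ≥
`minfpdiff`). `redock` runs n independent seeded GA runs and reports
per-run top-ranked and best-found symmetry-aware RMSD to the native
pose; `success_rate` is the fraction of runs whose top pose lies
strictly below a threshold. `rescore_pool` re-ranks a pose pool under
any scheme with a stable (energy, original index) sort.

## 7. Fixtures (`molsample.fixtures`)

Six deterministic systems support the tests: butane (torsion basins), a
cyclic dipeptide (ring opening, trigonal centers), a chiral probe, a
symmetric ligand with a carboxylate (equivalence and fingerprints), and
two ligand-in-cavity complexes — a hydrophobic barrel whose planted
pose is the global optimum under the fitted scheme, and a polar variant
with a hydrophobic decoy pocket that out-scores the planted polar pose
under the core scheme but not under the fitted one. A rigged scan set
with a unique winning hydrophobic triplet exercises the grid scan. All
fixtures are generated programmatically from a seed and regenerate
bit-identically.
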