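"""Rigid-site redocking protocol, pose post-processing and rescoring scan.

The workflow mirrors a classic redocking benchmark: cut a rigid binding
subdomain around a reference ligand, dock from an unbiased start conformer
in several independent seeded runs, post-filter each run's pose archive
(centroid and energy-window filters, exhaustive refinement, non-redundant
top-30 selection), and score success as the fraction of runs whose
top-ranked pose falls under a symmetry-compliant RMSD threshold.

The hydrophobic-constant triplet scan rescoREs fixed pose pools under every
combination of the discrete K grid (10^3 combinations).  The total energy
is affine in the three class constants, so each pose is decomposed once
into a K-free part and a 3x3 matrix of class-pair contact sums; the scan
itself is then a cheap tensor contraction.  A full-model slow path is kept
for cross-checking.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Atom, Bond, Molecule, assign_interaction_roles
from .evolution import EvolutionConfig, run as run_evolution
from .fingerprints import PIFLayout, build_layout, compute_pif, \
    pif_distance, symmetry_rmsd
from .forcefield import EnergyModel, assign_vdw_radii, triplet_energy
from .operators import SamplingContext, exhaustive_minimize
from .params import FFParameters, K_SCAN_VALUES, ParameterScheme

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC"}
SITE_RADIUS = 10.0          # residue-retention radius around the ligand
CENTROID_FILTER = 8.0       # poses with ligand centroid beyond this are dropped
ENERGY_WINDOW = 30.0        # kcal/mol above the best pose
MAX_POSES = 30
HOT_SPOT_RADIUS = 6.0


@dataclass
class BindingSite:
    """A rigid binding subdomain; every atom is fixed."""

    mol: Molecule
    center: np.ndarray
    hot_spots: list[int] = field(default_factory=list)


@dataclass
class Pose:
    coords: np.ndarray
    energy: float
    pif: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class PosePool:
    poses: list[Pose]

    def energies(self) -> np.ndarray:
        return np.array([p.energy for p in self.poses])

    def __len__(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# site preparation
# ---------------------------------------------------------------------------

def prepare_site(protein: Molecule, reference_coords: np.ndarray,
                 radius: float = SITE_RADIUS) -> BindingSite:
    """Cut the binding subdomain: complete residues near the ligand.

    A residue is kept when any of its atoms lies within ``radius`` (<=
    convention) of any reference-ligand atom.  Waters are removed; cofactors
    and ions are ordinary residues and therefore retained, fixed, at their
    experimental geometry.  Bonds crossing the subdomain boundary are
    dropped (the site is rigid, so no bonded term is needed across it).
    """
    ref = np.asarray(reference_coords, dtype=float)
    residues: dict[tuple[int, str], list[int]] = {}
    for a in protein.atoms:
        residues.setdefault((a.resid, a.resname), []).append(a.index)
    keep: list[int] = []
    for (resid, resname), members in residues.items():
        if resname.upper() in WATER_RESNAMES:
            continue
        d = np.linalg.norm(protein.coords[members][:, None, :]
                           - ref[None, :, :], axis=2)
        if d.min() <= radius:
            keep.extend(members)
    if not keep:
        raise ValueError("empty binding site: no residue within "
                         f"{radius} A of the reference ligand")
    keep = sorted(keep)
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for new, old in enumerate(keep):
        a = protein.atoms[old]
        atoms.append(Atom(index=new, element=a.element, ff_type=a.ff_type,
                          charge=a.charge, fixed=True, role=a.role,
                          hydro_class=a.hydro_class,
                          vdw_radius=a.vdw_radius,
                          formal_charge=a.formal_charge, name=a.name,
                          resid=a.resid, resname=a.resname))
    bonds = [Bond(i=remap[b.i], j=remap[b.j], order=b.order)
             for b in protein.bonds if b.i in remap and b.j in remap]
    site_mol = Molecule(atoms, bonds, protein.coords[keep])
    assign_interaction_roles(site_mol)
    heavy = site_mol.heavy_atoms()
    center = site_mol.coords[heavy].mean(axis=0) if len(heavy) else \
        site_mol.coords.mean(axis=0)
    site = BindingSite(mol=site_mol, center=center)
    site.hot_spots = auto_hot_spots(site)
    return site


def auto_hot_spots(site: BindingSite,
                   radius: float = HOT_SPOT_RADIUS) -> list[int]:
    """Putative contact centers: role atoms near the subdomain center."""
    eligible = [a.index for a in site.mol.atoms if a.role != "none"]
    d = np.linalg.norm(site.mol.coords - site.center, axis=1)
    spots = [i for i in eligible if d[i] <= radius]
    if not spots:
        warnings.warn("no hot spots within radius; using all eligible "
                      "site atoms")
        return eligible
    return spots


def assemble_complex(site: BindingSite, ligand: Molecule,
                     params: Optional[FFParameters] = None
                     ) -> tuple[Molecule, np.ndarray]:
    """Merge a fixed site and a free ligand into one system.

    Returns the combined molecule and the (new) ligand atom indices.  Hot
    spot indices of the site are valid unchanged (site atoms come first).
    """
    n_site = site.mol.n_atoms
    atoms = []
    for a in site.mol.atoms:
        atoms.append(Atom(index=a.index, element=a.element,
                          ff_type=a.ff_type, charge=a.charge, fixed=True,
                          role=a.role, hydro_class=a.hydro_class,
                          vdw_radius=a.vdw_radius,
                          formal_charge=a.formal_charge, name=a.name,
                          resid=a.resid, resname=a.resname))
    for a in ligand.atoms:
        atoms.append(Atom(index=n_site + a.index, element=a.element,
                          ff_type=a.ff_type, charge=a.charge, fixed=False,
                          role=a.role, hydro_class=a.hydro_class,
                          vdw_radius=a.vdw_radius,
                          formal_charge=a.formal_charge, name=a.name,
                          resid=a.resid, resname=a.resname))
    bonds = [Bond(i=b.i, j=b.j, order=b.order) for b in site.mol.bonds]
    bonds += [Bond(i=b.i + n_site, j=b.j + n_site, order=b.order,
                   declared_broken=b.declared_broken)
              for b in ligand.bonds]
    coords = np.vstack([site.mol.coords, ligand.coords])
    mol = Molecule(atoms, bonds, coords)
    assign_interaction_roles(mol)
    assign_vdw_radii(mol, params)
    return mol, np.arange(n_site, n_site + ligand.n_atoms)


# ---------------------------------------------------------------------------
# pose post-processing
# ---------------------------------------------------------------------------

def select_non_redundant(poses: Sequence[Pose], minfpdiff: float = 0.01,
                         max_poses: int = MAX_POSES) -> list[Pose]:
    """Greedy energy-sorted selection with pairwise delta >= minfpdiff."""
    ordered = sorted(poses, key=lambda p: p.energy)
    kept: list[Pose] = []
    for p in ordered:
        if all(pif_distance(p.pif, q.pif) >= minfpdiff for q in kept):
            kept.append(p)
        if len(kept) >= max_poses:
            break
    return kept


def filter_poses(ctx: SamplingContext, layout: PIFLayout,
                 poses: Sequence[Pose], site_center: np.ndarray,
                 ligand_atoms: Sequence[int],
                 rng: np.random.Generator,
                 window: float = ENERGY_WINDOW,
                 max_centroid: float = CENTROID_FILTER,
                 max_poses: int = MAX_POSES,
                 minfpdiff: float = 0.01,
                 refine: bool = True) -> PosePool:
    """Post-process one run's pose archive.

    Drops poses whose ligand centroid is more than ``max_centroid`` from
    the site center, keeps the +``window`` kcal/mol band above the best
    survivor, exhaustively refines the survivors, and returns the top
    ``max_poses`` non-redundant (delta >= minfpdiff) poses, energy-sorted.
    """
    if not poses:
        raise ValueError("empty pose pool")
    lig = np.asarray(ligand_atoms, dtype=int)
    survivors = [p for p in poses
                 if np.linalg.norm(p.coords[lig].mean(axis=0)
                                   - site_center) <= max_centroid]
    if not survivors:
        raise ValueError("no pose within the centroid filter")
    best = min(p.energy for p in survivors)
    survivors = [p for p in survivors if p.energy <= best + window]
    refined = []
    for p in survivors:
        if refine:
            x = exhaustive_minimize(ctx, p.coords, rng)
            refined.append(Pose(coords=x,
                                energy=ctx.model.energy(x).total,
                                pif=compute_pif(layout, x),
                                provenance=dict(p.provenance)))
        else:
            refined.append(p)
    return PosePool(poses=select_non_redundant(refined, minfpdiff,
                                               max_poses))


# ---------------------------------------------------------------------------
# redocking and success accounting
# ---------------------------------------------------------------------------

def redock(ctx: SamplingContext, layout: PIFLayout,
           start_coords: np.ndarray, reference_coords: np.ndarray,
           ligand_atoms: Sequence[int], site_center: np.ndarray,
           config: EvolutionConfig, n_runs: int = 10,
           base_seed: int = 0, refine: bool = True
           ) -> tuple[list[PosePool], pd.DataFrame]:
    """n_runs independent seeded evolution runs + per-run filtered pools.

    ``start_coords`` must be an unbiased start conformer (never the
    reference pose).  The summary lists, per run, the symmetry-RMSD of the
    top-ranked pose and of the best-sampled pose with respect to the
    reference, computed over ligand heavy atoms without superposition.
    """
    from dataclasses import replace as dc_replace
    lig = np.asarray(ligand_atoms, dtype=int)
    lig_heavy = np.array([i for i in lig
                          if ctx.mol.atoms[i].element != "H"], dtype=int)
    pools, rows = [], []
    for r in range(n_runs):
        cfg = dc_replace(config, seed=base_seed + r)
        result = run_evolution(ctx, layout, cfg, start_coords)
        archive_poses = [Pose(coords=m.coords, energy=m.energy, pif=m.pif,
                              provenance={"run": r, "seed": cfg.seed})
                         for m in result.archive]
        rng = np.random.default_rng(cfg.seed + 10 ** 6)
        pool = filter_poses(ctx, layout, archive_poses, site_center, lig,
                            rng, minfpdiff=cfg.minfpdiff, refine=refine)
        pools.append(pool)
        rmsds = [symmetry_rmsd(ctx.mol, p.coords, reference_coords,
                               atom_subset=lig_heavy) for p in pool.poses]
        rows.append({"run": r, "seed": cfg.seed,
                     "top_energy": pool.poses[0].energy,
                     "top_rmsd": rmsds[0],
                     "best_rmsd": min(rmsds),
                     "n_poses": len(pool)})
    return pools, pd.DataFrame(rows)


def success_rate(rmsds_per_complex: Sequence[Sequence[float]],
                 threshold: float) -> float:
    """Sum of per-run successes over (runs x complexes).

    One complex with 6/10 runs under the threshold contributes 6 successes
    and 4 failures; the average is total successes / total runs.
    """
    total, hits = 0, 0
    for runs in rmsds_per_complex:
        for r in runs:
            total += 1
            if r < threshold:
                hits += 1
    return hits / total if total else 0.0


# ---------------------------------------------------------------------------
# rescoring and the K-triplet scan
# ---------------------------------------------------------------------------

def rescore_pool(mol: Molecule, pool: PosePool, scheme: ParameterScheme,
                 params: Optional[FFParameters] = None) -> PosePool:
    """Recompute pose energies under a scheme without re-minimization.

    Ranking is a pure function of the scheme; ties break by pose id
    (stable sort).
    """
    model = EnergyModel(mol, scheme, params)
    rescored = [Pose(coords=p.coords,
                     energy=model.energy(p.coords).total,
                     pif=p.pif, provenance=dict(p.provenance))
                for p in pool.poses]
    order = sorted(range(len(rescored)),
                   key=lambda i: (rescored[i].energy, i))
    return PosePool(poses=[rescored[i] for i in order])


@dataclass
class ScanComplex:
    """Precomputed per-complex inputs for the triplet scan."""

    name: str
    e_zero_k: np.ndarray        # (n_poses,) energies with all K = 0
    s_matrices: np.ndarray      # (n_poses, 3, 3) class-pair contact sums
    rmsd: np.ndarray            # (n_poses,) symmetry-RMSD vs native


def prepare_scan_complex(name: str, mol: Molecule, pool: PosePool,
                         reference_coords: np.ndarray,
                         ligand_atoms: Sequence[int],
                         scheme: ParameterScheme,
                         params: Optional[FFParameters] = None
                         ) -> ScanComplex:
    """Decompose each pose once; the scan is then K-free arithmetic."""
    model = EnergyModel(mol, scheme.with_triplet(0.0, 0.0, 0.0), params)
    lig_heavy = np.array([i for i in np.asarray(ligand_atoms, dtype=int)
                          if mol.atoms[i].element != "H"], dtype=int)
    e0, S, rmsd = [], [], []
    for p in pool.poses:
        e, s = model.hydrophobic_decomposition(p.coords)
        e0.append(e)
        S.append(s)
        rmsd.append(symmetry_rmsd(mol, p.coords, reference_coords,
                                  atom_subset=lig_heavy))
    return ScanComplex(name=name, e_zero_k=np.array(e0),
                       s_matrices=np.array(S), rmsd=np.array(rmsd))


@dataclass
class ScanResult:
    table: pd.DataFrame             # one row per triplet with success count
    winners: list[tuple[float, float, float]]
    best_count: int
    selected: tuple[float, float, float]


def scan_triplets(complexes: Sequence[ScanComplex],
                  grid: Sequence[float] = K_SCAN_VALUES,
                  rmsd_threshold: float = 2.0) -> ScanResult:
    """Exhaustive scan of (K_polarized, K_arom, K_aliph) combinations.

    For every triplet, each complex's pool is rescored (fast affine path)
    and counts as a success when the top-ranked pose lies under the RMSD
    threshold.  The kept combination is taken at the core of the winning
    region: the component-wise median over all winning triplets, snapped to
    the grid.
    """
    rows = []
    for kp, ka, kl in itertools.product(grid, grid, grid):
        successes = 0
        for c in complexes:
            energies = np.array([triplet_energy(e, s, (kp, ka, kl))
                                 for e, s in zip(c.e_zero_k, c.s_matrices)])
            top = int(np.argmin(energies))  # argmin is stable: first minimum
            if c.rmsd[top] < rmsd_threshold:
                successes += 1
        rows.append({"k_polarized": kp, "k_arom": ka, "k_aliph": kl,
                     "successes": successes})
    table = pd.DataFrame(rows)
    best_count = int(table["successes"].max())
    win = table[table["successes"] == best_count]
    winners = [(r.k_polarized, r.k_arom, r.k_aliph)
               for r in win.itertuples()]
    grid_arr = np.asarray(grid)

    def snap(x: float) -> float:
        return float(grid_arr[np.argmin(np.abs(grid_arr - x))])

    selected = (snap(float(np.median([w[0] for w in winners]))),
                snap(float(np.median([w[1] for w in winners]))),
                snap(float(np.median([w[2] for w in winners]))))
    return ScanResult(table=table, winners=winners,
                      best_count=best_count, selected=selected)


def rescore_with_triplet(mol: Molecule, pool: PosePool,
                         scheme: ParameterScheme,
                         triplet: tuple[float, float, float],
                         params: Optional[FFParameters] = None
                         ) -> np.ndarray:
    """Slow cross-check path: full model rebuild for one triplet."""
    model = EnergyModel(mol, scheme.with_triplet(*triplet), params)
    return np.array([model.energy(p.coords).total for p in pool.poses])
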