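"""Differentiable pairwise interaction fingerprints (PIF) and symmetry-RMSD.

A PIF monitors, for every eligible pair of symmetry sets (both hydrophobic,
or donor vs acceptor, topologically separated by more than 5 bonds, with at
least one non-fixed atom), the self-weighted average of the member-pair
contact strengths:

    PIF_k = sum(C_ij^2) / sum(C_ij)     (0 when every C_ij = 0)

C is the unit-amplitude switching function of the contact terms (the kappa
prefactor is stripped, so PIF elements live in [0,1] regardless of the
parameter scheme).  The self-weighting biases the average toward strong
contacts and keeps the fingerprint differentiable, unlike a max.

The size-relative block distance delta(a, b) = sum|a_k - b_k| / N_F is the
generic fraction of monitored contacts whose status differs, and drives the
population-diversity machinery (redundancy below ``minfpdiff``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import Molecule, SymmetrySet, build_symmetry_sets, set_topo_distance
from .forcefield import HBOND_RANGE_DELTA, HYDROPHOBIC_RANGE, contact_switch

MIN_TOPO_SEPARATION = 5  # pairs must satisfy T(s, S) > 5


@dataclass
class PIFLayout:
    """Ordered list of monitored symmetry-set pairs; geometry-independent."""

    set_pairs: list[tuple[SymmetrySet, SymmetrySet]]
    roles: list[str]                       # "hydrophobic" | "hbond"
    # flattened member-pair arrays for vectorized evaluation
    pair_i: np.ndarray = field(default=None, repr=False)
    pair_j: np.ndarray = field(default=None, repr=False)
    dmin2: np.ndarray = field(default=None, repr=False)
    dmax2: np.ndarray = field(default=None, repr=False)
    segment: np.ndarray = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return len(self.set_pairs)

    def describe(self) -> str:
        lines = ["k\trole\tset_A_members\tset_B_members"]
        for k, ((sa, sb), role) in enumerate(zip(self.set_pairs, self.roles)):
            lines.append(f"{k}\t{role}\t"
                         f"{','.join(str(m + 1) for m in sa.members)}\t"
                         f"{','.join(str(m + 1) for m in sb.members)}")
        return "\n".join(lines)


def build_layout(mol: Molecule,
                 symmetry_sets: Optional[Sequence[SymmetrySet]] = None
                 ) -> PIFLayout:
    """Enumerate the monitored set pairs (intra- and intermolecular).

    Eligible pairs: hydrophobe set with hydrophobe set (including a set with
    itself when its members are mutually remote), or donor set with acceptor
    set; topological separation T > 5 (999 across components qualifies);
    not all atoms of both sets fixed.
    """
    if symmetry_sets is None:
        symmetry_sets = build_symmetry_sets(mol, typed_only=True)
    fixed = mol.fixed_mask
    vdw = np.array([a.vdw_radius for a in mol.atoms])
    set_pairs, roles = [], []
    pi, pj, dm2, dx2, seg = [], [], [], [], []
    for a in range(len(symmetry_sets)):
        for b in range(a, len(symmetry_sets)):
            sa, sb = symmetry_sets[a], symmetry_sets[b]
            if sa.role == "hydrophobe" and sb.role == "hydrophobe":
                role = "hydrophobic"
            elif {sa.role, sb.role} == {"donor_H", "acceptor"}:
                role = "hbond"
            else:
                continue
            if set_topo_distance(mol, sa, sb) <= MIN_TOPO_SEPARATION:
                continue
            if all(fixed[m] for m in sa.members) and \
               all(fixed[m] for m in sb.members):
                continue
            if a == b:
                members = [(i, j) for i, j in
                           itertools.combinations(sa.members, 2)]
            else:
                members = [(i, j) for i in sa.members for j in sb.members]
            k = len(set_pairs)
            set_pairs.append((sa, sb))
            roles.append(role)
            for i, j in members:
                pi.append(i)
                pj.append(j)
                if role == "hydrophobic":
                    lo, hi = HYDROPHOBIC_RANGE
                else:
                    sv = vdw[i] + vdw[j]
                    lo, hi = sv + HBOND_RANGE_DELTA[0], sv + HBOND_RANGE_DELTA[1]
                dm2.append(lo * lo)
                dx2.append(hi * hi)
                seg.append(k)
    return PIFLayout(set_pairs=set_pairs, roles=roles,
                     pair_i=np.array(pi, dtype=int),
                     pair_j=np.array(pj, dtype=int),
                     dmin2=np.array(dm2), dmax2=np.array(dx2),
                     segment=np.array(seg, dtype=int))


def compute_pif(layout: PIFLayout, coords: np.ndarray) -> np.ndarray:
    """PIF vector in [0,1]^N_F for one geometry."""
    nf = layout.n_features
    if nf == 0 or len(layout.pair_i) == 0:
        return np.zeros(nf)
    dvec = coords[layout.pair_i] - coords[layout.pair_j]
    d2 = np.einsum("ij,ij->i", dvec, dvec)
    c = contact_switch(d2, layout.dmin2, layout.dmax2)
    num = np.bincount(layout.segment, weights=c * c, minlength=nf)
    den = np.bincount(layout.segment, weights=c, minlength=nf)
    out = np.zeros(nf)
    nz = den > 1e-12
    out[nz] = num[nz] / den[nz]
    return out


def pif_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Size-relative block distance: fraction of contacts with changed status."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fingerprints come from different layouts")
    if len(a) == 0:
        return 0.0
    return float(np.mean(np.abs(a - b)))


ORIGINALITY_MAX = float("inf")  # sentinel for the globally fittest individual


def originality(energy: float, pif: np.ndarray,
                pop_energies: Sequence[float],
                pop_pifs: Sequence[np.ndarray]) -> float:
    """Smallest PIF distance to any strictly fitter individual.

    The fittest individual has no fitter rival and is assigned the sentinel
    maximum (it is never targeted by the diversity routines).  An empty
    fingerprint carries no redundancy evidence, so every member gets the
    sentinel and the diversity machinery is inert.
    """
    if len(np.asarray(pif)) == 0:
        return ORIGINALITY_MAX
    best = ORIGINALITY_MAX
    for e, p in zip(pop_energies, pop_pifs):
        if e < energy:
            d = pif_distance(pif, p)
            if d < best:
                best = d
    return best


# ---------------------------------------------------------------------------
# symmetry-compliant RMSD
# ---------------------------------------------------------------------------

def symmetry_rmsd(mol: Molecule, coords_a: np.ndarray, coords_b: np.ndarray,
                  atom_subset: Optional[Sequence[int]] = None,
                  brute_force: bool = False) -> float:
    """Minimum RMSD over within-symmetry-set atom permutations, no fitting.

    No superposition is applied (docking convention: the site frame is
    fixed).  Heavy atoms by default.  The within-set minimization is solved
    exactly, per set, as a linear assignment problem (costs are separable
    across sets); ``brute_force`` enumerates permutations instead and is
    kept as an independent oracle for small molecules.
    """
    if atom_subset is None:
        atom_subset = mol.heavy_atoms()
    subset = np.asarray(atom_subset, dtype=int)
    if len(subset) == 0:
        return 0.0
    part = build_symmetry_sets(mol, typed_only=False)
    in_subset = set(subset.tolist())
    groups = [[m for m in s.members if m in in_subset] for s in part]
    groups = [g for g in groups if g]
    if brute_force:
        return _brute_force_rmsd(groups, coords_a, coords_b, len(subset))
    total = 0.0
    for g in groups:
        if len(g) == 1:
            total += float(np.sum((coords_a[g[0]] - coords_b[g[0]]) ** 2))
            continue
        ga = coords_a[g]
        gb = coords_b[g]
        cost = np.sum((ga[:, None, :] - gb[None, :, :]) ** 2, axis=2)
        rows, cols = linear_sum_assignment(cost)
        total += float(cost[rows, cols].sum())
    return math_sqrt(total / len(subset))


def _brute_force_rmsd(groups, coords_a, coords_b, n) -> float:
    import itertools as it
    counts = 1
    for g in groups:
        for m in range(2, len(g) + 1):
            counts *= m
        if counts > 10 ** 4:
            raise ValueError("too many permutations for brute force")
    best = None
    perms_per_group = [list(it.permutations(g)) for g in groups]
    for combo in it.product(*perms_per_group):
        total = 0.0
        for g, perm in zip(groups, combo):
            total += float(np.sum((coords_a[list(perm)] - coords_b[g]) ** 2))
        if best is None or total < best:
            best = total
    return math_sqrt(best / n)


def math_sqrt(x: float) -> float:
    return float(np.sqrt(max(x, 0.0)))
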