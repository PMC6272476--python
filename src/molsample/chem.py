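"""Molecular data model.

A :class:`Molecule` is the universal substrate of the sampler: an atom graph
with Cartesian coordinates, force-field types and partial charges, per-atom
flexibility flags, rotatable-bond / fragment decomposition and symmetry-set
(topological equivalence) analysis.  Everything downstream -- the force field,
the interaction fingerprints and the genetic operators -- consumes this object.

Conventions: distances in Angstrom, charges in electrons, 0-based atom
indexing in memory (1-based only in file I/O).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

# Topological distance assigned across disjoint molecular components.
DISJOINT_T = 999

# H-bond donor hydrogens and acceptor heavy atoms by AMBER/GAFF type.
DONOR_H_TYPES = {"H", "HO", "HW", "hn", "ho", "hw"}
ACCEPTOR_TYPES = {
    "O", "O2", "OW", "OH", "OS", "NB", "NC", "NY",
    "o", "oh", "os", "ow",
    "n1", "n2", "n3", "na", "nb", "nc", "nd", "ne", "nf",
}

# Hydrophobic carbon classes (AMBER + GAFF types).
CARBON_CLASSES = {
    # polarized
    "C": "polarized", "c": "polarized",
    # aromatic
    "C*": "aromatic", "CA": "aromatic", "CB": "aromatic", "CC": "aromatic",
    "CN": "aromatic", "CR": "aromatic", "CV": "aromatic", "CW": "aromatic",
    "ca": "aromatic", "cc": "aromatic", "cd": "aromatic",
    "cp": "aromatic", "cq": "aromatic",
    # aliphatic
    "CT": "aliphatic", "c1": "aliphatic", "c2": "aliphatic", "c3": "aliphatic",
    "ce": "aliphatic", "cf": "aliphatic", "cg": "aliphatic", "ch": "aliphatic",
    "cu": "aliphatic", "cv": "aliphatic", "cx": "aliphatic", "cy": "aliphatic",
}

# Monoatomic metal cations eligible for the ion desolvation scaling.
METAL_ELEMENTS = {"Zn", "Mg", "Ca", "Mn", "Fe", "Na", "K", "Cu", "Ni", "Co", "Li"}

CHARGE_TOL = 1e-4  # equality tolerance when bucketing charges for symmetry sets


@dataclass
class Atom:
    index: int
    element: str
    ff_type: str = ""
    charge: float = 0.0
    fixed: bool = False
    role: str = "none"          # donor_H | acceptor | hydrophobe | none
    hydro_class: Optional[str] = None  # polarized | aromatic | aliphatic
    vdw_radius: float = 1.5     # r* in Angstrom, filled from the parameter set
    formal_charge: int = 0
    name: str = ""
    resid: int = 1
    resname: str = "LIG"


@dataclass
class Bond:
    i: int
    j: int
    order: int = 1
    is_amide: bool = False
    in_ring: bool = False
    declared_broken: bool = False

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Fragment:
    """Operand of the genetic operators.

    A *bound* fragment is the moiety on one side of a rotatable (pivot) bond;
    a *loose* fragment is a whole disjoint component free of fixed atoms
    (typically a ligand) that moves relative to the rest of the system.
    """

    atom_set: frozenset[int]
    kind: str                       # "bound" | "loose"
    pivot_bond: Optional[tuple[int, int]] = None  # (in-fragment atom, complement atom)
    complement: frozenset[int] = frozenset()


@dataclass
class SymmetrySet:
    """Equivalence class of topologically identical atoms."""

    id: int
    members: tuple[int, ...]
    role: str = "none"
    hydro_class: Optional[str] = None
    charge: float = 0.0


class Molecule:
    """Atom graph + coordinates + typing + flexibility status.

    ``coords`` holds the reference geometry; operators work on detached
    coordinate arrays of the same shape.
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[Bond],
                 coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.coords = coords.copy()
        self._rebuild_graph()

    # -- construction helpers ------------------------------------------------

    def _rebuild_graph(self) -> None:
        n = len(self.atoms)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        self.graph = g
        comps = [frozenset(c) for c in nx.connected_components(g)]
        # deterministic ordering by smallest member
        self.components = sorted(comps, key=min)
        self._comp_of = np.empty(n, dtype=int)
        for ci, comp in enumerate(self.components):
            for a in comp:
                self._comp_of[a] = ci
        self.topo_dist = self._compute_topo_dist()
        self._perceive_rings()
        self._perceive_amides()

    def _compute_topo_dist(self) -> np.ndarray:
        n = len(self.atoms)
        rows = [b.i for b in self.bonds] + [b.j for b in self.bonds]
        cols = [b.j for b in self.bonds] + [b.i for b in self.bonds]
        data = np.ones(len(rows))
        adj = csr_matrix((data, (rows, cols)), shape=(n, n))
        d = shortest_path(adj, method="D", unweighted=True, directed=False)
        d[~np.isfinite(d)] = DISJOINT_T
        return d.astype(int)

    def _perceive_rings(self) -> None:
        """Smallest-set-of-smallest-rings style perception via cycle basis."""
        ring_edges: set[tuple[int, int]] = set()
        for comp in self.components:
            sub = self.graph.subgraph(comp)
            for cycle in nx.minimum_cycle_basis(sub):
                cyc = list(cycle)
                csub = self.graph.subgraph(cyc)
                for u, v in csub.edges():
                    ring_edges.add((u, v) if u < v else (v, u))
        self._ring_edges = ring_edges
        for b in self.bonds:
            b.in_ring = b.key() in ring_edges

    def _perceive_amides(self) -> None:
        """Amide = N single-bonded to a C that is double-bonded to an O."""
        order = {}
        for b in self.bonds:
            order[b.key()] = b.order
        for b in self.bonds:
            ei, ej = self.atoms[b.i].element, self.atoms[b.j].element
            if b.order != 1 or {ei, ej} != {"C", "N"}:
                b.is_amide = False
                continue
            c = b.i if ei == "C" else b.j
            carbonyl = any(
                self.atoms[nb].element == "O"
                and order[(min(c, nb), max(c, nb))] == 2
                for nb in self.graph.neighbors(c)
            )
            b.is_amide = carbonyl

    # -- basic queries -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def fixed_mask(self) -> np.ndarray:
        mask = getattr(self, "_fixed_mask", None)
        if mask is None:
            mask = np.array([a.fixed for a in self.atoms], dtype=bool)
            self._fixed_mask = mask
        return mask

    @property
    def free_atoms(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed_mask)

    def component_of(self, i: int) -> int:
        return int(self._comp_of[i])

    def set_fixed(self, indices: Iterable[int], fixed: bool = True) -> None:
        for i in indices:
            self.atoms[i].fixed = fixed
        self._fixed_mask = None

    def is_metal_cation(self, i: int) -> bool:
        a = self.atoms[i]
        comp = self.components[self._comp_of[i]]
        return (len(comp) == 1 and a.element in METAL_ELEMENTS
                and a.formal_charge >= 1)

    def heavy_atoms(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.element != "H"],
                        dtype=int)


# ---------------------------------------------------------------------------
# interaction roles
# ---------------------------------------------------------------------------

def assign_interaction_roles(mol: Molecule) -> Molecule:
    """Label each atom donor_H / acceptor / hydrophobe(class) / none.

    The assignment is a pure function of the force-field type: polar
    hydrogens are donors, the listed O/N types acceptors, and carbons fall
    into the polarized / aromatic / aliphatic hydrophobe classes.  Types
    outside the lists get role ``none``.
    """
    known_prefixes = ("h", "H", "c", "C", "n", "N", "o", "O", "s", "S", "p", "P",
                     "f", "F", "b", "B", "i", "I", "Z", "M", "K", "L", "x", "X")
    for a in mol.atoms:
        t = a.ff_type
        if t in DONOR_H_TYPES:
            a.role, a.hydro_class = "donor_H", None
        elif t in ACCEPTOR_TYPES:
            a.role, a.hydro_class = "acceptor", None
        elif t in CARBON_CLASSES:
            a.role, a.hydro_class = "hydrophobe", CARBON_CLASSES[t]
        else:
            if t and not t.startswith(known_prefixes):
                warnings.warn(f"unknown force-field type {t!r} on atom "
                              f"{a.index}; interaction role set to none")
            a.role, a.hydro_class = "none", None
    return mol


# ---------------------------------------------------------------------------
# rotatable bonds and fragments
# ---------------------------------------------------------------------------

def detect_rotatable_bonds(mol: Molecule, exclude_amide: bool = True
                           ) -> list[Bond]:
    """Exocyclic single bonds between non-terminal atoms.

    Amide C-N bonds are excluded by default.  Ring bonds are excluded unless
    explicitly declared broken (ring sampling / loop activation), in which
    case they are listed here while their harmonic bond term stays intact.
    """
    out = []
    deg = dict(mol.graph.degree())
    for b in mol.bonds:
        if b.declared_broken:
            out.append(b)
            continue
        if b.order != 1 or b.in_ring:
            continue
        if exclude_amide and b.is_amide:
            continue
        if deg[b.i] < 2 or deg[b.j] < 2:
            continue
        out.append(b)
    return out


def _moieties(mol: Molecule, bond: Bond) -> Optional[tuple[set[int], set[int]]]:
    """Split the graph (minus all declared-broken bonds) at ``bond``."""
    g = mol.graph.copy()
    for b in mol.bonds:
        if b.declared_broken and g.has_edge(b.i, b.j):
            g.remove_edge(b.i, b.j)
    if g.has_edge(bond.i, bond.j):
        g.remove_edge(bond.i, bond.j)
    side_i = nx.node_connected_component(g, bond.i)
    if bond.j in side_i:
        return None  # still connected (e.g. the broken ring bond itself)
    side_j = nx.node_connected_component(g, bond.j)
    return set(side_i), set(side_j)


def build_fragments(mol: Molecule, min_size: int = 5,
                    rotatable: Optional[Sequence[Bond]] = None,
                    exclude_amide: bool = True) -> list[Fragment]:
    """Fragment decomposition.

    For every rotatable bond, the smaller fixed-atom-free moiety of at least
    ``min_size`` atoms becomes a bound fragment.  Each disjoint component
    without fixed atoms additionally becomes one loose fragment.  Atoms in no
    fragment and not fixed are passive (they still relax under gradient
    optimization).
    """
    if rotatable is None:
        rotatable = detect_rotatable_bonds(mol, exclude_amide=exclude_amide)
    fixed = mol.fixed_mask
    frags: list[Fragment] = []
    for b in rotatable:
        sides = _moieties(mol, b)
        if sides is None:
            continue
        eligible = [s for s in sides
                    if not any(fixed[a] for a in s) and len(s) >= min_size]
        if not eligible:
            continue
        side = min(eligible, key=lambda s: (len(s), min(s)))
        other = sides[0] if side is sides[1] else sides[1]
        fa = b.i if b.i in side else b.j
        fb = b.j if fa == b.i else b.i
        frags.append(Fragment(atom_set=frozenset(side), kind="bound",
                              pivot_bond=(fa, fb),
                              complement=frozenset(other)))
    all_atoms = frozenset(range(mol.n_atoms))
    for comp in mol.components:
        if not any(fixed[a] for a in comp):
            frags.append(Fragment(atom_set=frozenset(comp), kind="loose",
                                  pivot_bond=None,
                                  complement=all_atoms - comp))
    return frags


# ---------------------------------------------------------------------------
# symmetry sets
# ---------------------------------------------------------------------------

def _equivalence_partition(mol: Molecule) -> np.ndarray:
    """Morgan-style iterated refinement seeded by (element, charge bucket).

    After the neighbourhood refinement reaches a fixed point, classes are
    further split by their sorted multiset of topological distances to every
    refined class, which makes the partition permutation-invariant and
    reproduces carboxylate / guanidinium equivalences.
    """
    n = mol.n_atoms
    labels = [
        (a.element, int(round(a.charge / CHARGE_TOL)))
        for a in mol.atoms
    ]
    order = {}
    for b in mol.bonds:
        order[b.key()] = b.order
    lab_ids = _canonical_ids(labels)
    while True:
        new = []
        for i in range(n):
            nbrs = sorted(
                (order[(min(i, j), max(i, j))], lab_ids[j])
                for j in mol.graph.neighbors(i)
            )
            new.append((lab_ids[i], tuple(nbrs)))
        new_ids = _canonical_ids(new)
        if np.array_equal(new_ids, lab_ids):
            break
        lab_ids = new_ids
    # distance-multiset split
    T = mol.topo_dist
    final = []
    for i in range(n):
        profile = sorted(zip(T[i], lab_ids))
        final.append((lab_ids[i], tuple(profile)))
    return _canonical_ids(final)


def _canonical_ids(labels: list) -> np.ndarray:
    # first-occurrence numbering: identical partitions always map to
    # identical id arrays, so the refinement fixpoint test is well defined
    uniq: dict = {}
    out = []
    for lab in labels:
        if lab not in uniq:
            uniq[lab] = len(uniq)
        out.append(uniq[lab])
    return np.array(out, dtype=int)


def build_symmetry_sets(mol: Molecule, typed_only: bool = True
                        ) -> list[SymmetrySet]:
    """Partition atoms into classes of topologically equivalent atoms.

    With ``typed_only`` (default) only atoms carrying an interaction role
    (donor / acceptor / hydrophobe) are returned -- the basis of the
    interaction fingerprint.  With ``typed_only=False`` the full partition is
    returned (used by the symmetry-compliant RMSD).
    """
    part = _equivalence_partition(mol)
    groups: dict[int, list[int]] = {}
    for i, cls in enumerate(part):
        groups.setdefault(int(cls), []).append(i)
    sets = []
    for cls in sorted(groups, key=lambda c: min(groups[c])):
        members = tuple(sorted(groups[cls]))
        a0 = mol.atoms[members[0]]
        if typed_only and a0.role == "none":
            continue
        sets.append(SymmetrySet(id=len(sets), members=members, role=a0.role,
                                hydro_class=a0.hydro_class, charge=a0.charge))
    return sets


def set_topo_distance(mol: Molecule, s1: SymmetrySet, s2: SymmetrySet) -> int:
    """Topological distance between two symmetry sets.

    For equivalence classes this is single-valued over member pairs; the
    minimum is used so that a hypothetical non-constant case errs on the
    conservative (exclude-from-fingerprint) side.
    """
    T = mol.topo_dist
    pairs = [(i, j) for i in s1.members for j in s2.members if i != j]
    if not pairs:
        return 0
    return int(min(T[i, j] for i, j in pairs))
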