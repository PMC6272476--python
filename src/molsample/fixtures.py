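"""Deterministic toy systems for testing and demonstration.

Every fixture is generated programmatically from (name, seed): analytic
starting geometries are relaxed with the seeded exhaustive minimizer, so
regeneration is bit-identical and no binary data ships with the package.

Available fixtures:

* ``butane``            -- n-butane; the classic one-torsion test system.
* ``cyclic_dipeptide``  -- glycine diketopiperazine; amide perception,
  ring handling and trigonal out-of-plane restraints.
* ``chiral_probe``      -- CHFClBr; a single stereocenter for the
  chirality-penalty sign convention.
* ``symmetric_ligand``  -- 4-propylbenzoate; carboxylate and aromatic
  symmetry sets with topologically remote hydrophobic pairs.
* ``cavity_hydrophobic``-- a rigid slot cavity (two plates + wall ring of
  fixed carbon pseudo-atoms) with a planted benzene pose.
* ``cavity_polar_decoy``-- the slot cavity with a wall acceptor plus a
  remote surface patch carrying exaggerated negative charges; a phenol
  ligand has one buried, H-bonded planted pose and one shallow decoy pose
  rewarded only by the fake ionic contacts.

A separate constructed oracle, :func:`make_rigged_scan_set`, produces
synthetic pose decompositions whose rescoring scan is won by exactly one
hydrophobic-constant triplet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem import Atom, Bond, Molecule, assign_interaction_roles
from .forcefield import assign_vdw_radii
from .io import element_of_type
from .operators import SamplingContext, exhaustive_minimize
from .params import get_scheme
from .pipeline import BindingSite, ScanComplex, assemble_complex, \
    auto_hot_spots

FIXTURE_NAMES = ("butane", "cyclic_dipeptide", "chiral_probe",
                 "symmetric_ligand", "cavity_hydrophobic",
                 "cavity_polar_decoy")


@dataclass
class Fixture:
    name: str
    seed: int
    mol: Molecule                       # molecule, or full site+ligand system
    scheme_name: str
    planted: Optional[np.ndarray] = None   # relaxed reference coordinates
    decoy: Optional[np.ndarray] = None     # alternative (decoy) pose
    start: Optional[np.ndarray] = None     # unbiased docking start coords
    ligand_atoms: Optional[np.ndarray] = None
    site_center: Optional[np.ndarray] = None
    hot_spots: Optional[list[int]] = None
    extras: dict = field(default_factory=dict)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    builders = {
        "butane": _butane,
        "cyclic_dipeptide": _cyclic_dipeptide,
        "chiral_probe": _chiral_probe,
        "symmetric_ligand": _symmetric_ligand,
        "cavity_hydrophobic": _cavity_hydrophobic,
        "cavity_polar_decoy": _cavity_polar_decoy,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"choose from {FIXTURE_NAMES}")
    return builders[name](seed)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

TETRA = math.radians(109.471)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _perp(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, trial)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, trial))


def tetrahedral_dirs(existing: list[np.ndarray], n_new: int
                     ) -> list[np.ndarray]:
    """Unit directions completing an (approximately) tetrahedral center."""
    ex = [_unit(e) for e in existing]
    if len(ex) == 0:
        base = [np.array([1.0, 1.0, 1.0]), np.array([1.0, -1.0, -1.0]),
                np.array([-1.0, 1.0, -1.0]), np.array([-1.0, -1.0, 1.0])]
        return [_unit(b) for b in base[:n_new]]
    if len(ex) == 1:
        u = ex[0]
        p, q = _perp(u), _unit(np.cross(u, _perp(u)))
        out = []
        for k in range(n_new):
            phi = 2.0 * math.pi * k / 3.0
            out.append(_unit(math.cos(TETRA) * u
                             + math.sin(TETRA) * (math.cos(phi) * p
                                                  + math.sin(phi) * q)))
        return out
    if len(ex) == 2:
        bis = -_unit(ex[0] + ex[1])
        axis = _unit(np.cross(ex[0], ex[1]))
        half = TETRA / 2.0
        dirs = [_unit(math.cos(half) * bis + math.sin(half) * axis),
                _unit(math.cos(half) * bis - math.sin(half) * axis)]
        return dirs[:n_new]
    return [-_unit(sum(ex))][:n_new]


class _Builder:
    """Incremental molecule assembly."""

    def __init__(self):
        self.types: list[str] = []
        self.charges: list[float] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[Bond] = []
        self.fixed: list[bool] = []
        self.formal: list[int] = []
        self.resids: list[int] = []
        self.resnames: list[str] = []

    def add(self, ff_type: str, charge: float, xyz, fixed: bool = False,
            formal: int = 0, resid: int = 1, resname: str = "LIG") -> int:
        self.types.append(ff_type)
        self.charges.append(charge)
        self.coords.append(np.asarray(xyz, dtype=float))
        self.fixed.append(fixed)
        self.formal.append(formal)
        self.resids.append(resid)
        self.resnames.append(resname)
        return len(self.types) - 1

    def bond(self, i: int, j: int, order: int = 1) -> None:
        self.bonds.append(Bond(i=i, j=j, order=order))

    def add_hydrogens(self, heavy: int, n: int, ff_type: str,
                      charge: float, length: float = 1.092) -> list[int]:
        center = self.coords[heavy]
        existing = []
        for b in self.bonds:
            if heavy in (b.i, b.j):
                other = b.j if b.i == heavy else b.i
                existing.append(self.coords[other] - center)
        out = []
        for d in tetrahedral_dirs(existing, n):
            h = self.add(ff_type, charge, center + length * d,
                         resid=self.resids[heavy],
                         resname=self.resnames[heavy])
            self.bond(heavy, h)
            existing.append(length * d)
            out.append(h)
        return out

    def build(self) -> Molecule:
        atoms = [Atom(index=i, element=element_of_type(t), ff_type=t,
                      charge=q, fixed=f, formal_charge=fc, resid=r,
                      resname=rn, name=f"{element_of_type(t)}{i + 1}")
                 for i, (t, q, f, fc, r, rn) in enumerate(
                     zip(self.types, self.charges, self.fixed, self.formal,
                         self.resids, self.resnames))]
        mol = Molecule(atoms, self.bonds, np.array(self.coords))
        assign_interaction_roles(mol)
        assign_vdw_radii(mol)
        return mol


def _relax(mol: Molecule, scheme_name: str, seed: int,
           coords: Optional[np.ndarray] = None,
           max_cycles: int = 6) -> tuple[SamplingContext, np.ndarray]:
    ctx = SamplingContext(mol, get_scheme(scheme_name))
    rng = np.random.default_rng(seed)
    x = exhaustive_minimize(ctx, mol.coords if coords is None else coords,
                            rng, max_cycles=max_cycles)
    return ctx, x


# ---------------------------------------------------------------------------
# small molecules
# ---------------------------------------------------------------------------

def _butane(seed: int) -> Fixture:
    b = _Builder()
    length, theta = 1.535, math.radians(111.6)
    sx, cz = math.sin(theta / 2.0), math.cos(theta / 2.0)
    carbons = []
    for i in range(4):
        xyz = (i * length * sx, 0.0, (i % 2) * length * cz)
        q = -0.09 if i in (0, 3) else -0.06
        carbons.append(b.add("c3", q, xyz))
    for i in range(3):
        b.bond(carbons[i], carbons[i + 1])
    b.add_hydrogens(carbons[0], 3, "hc", 0.03)
    b.add_hydrogens(carbons[1], 2, "hc", 0.03)
    b.add_hydrogens(carbons[2], 2, "hc", 0.03)
    b.add_hydrogens(carbons[3], 3, "hc", 0.03)
    mol = b.build()
    _, relaxed = _relax(mol, "core", seed)
    mol.coords = relaxed
    return Fixture(name="butane", seed=seed, mol=mol, scheme_name="core",
                   planted=relaxed,
                   extras={"torsion_quad": (0, 1, 2, 3)})


def _cyclic_dipeptide(seed: int) -> Fixture:
    b = _Builder()
    radius = 1.40
    kinds = [("n", -0.42), ("c", 0.60), ("c3", -0.02),
             ("n", -0.42), ("c", 0.60), ("c3", -0.02)]
    ring = []
    for k, (t, q) in enumerate(kinds):
        ang = math.pi / 3.0 * k
        ring.append(b.add(t, q, (radius * math.cos(ang),
                                 radius * math.sin(ang), 0.0)))
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6])
    for k, (t, _q) in enumerate(kinds):
        out = _unit(np.array(b.coords[ring[k]]))
        if t == "c":
            o = b.add("o", -0.57, b.coords[ring[k]] + 1.22 * out)
            b.bond(ring[k], o, order=2)
        elif t == "n":
            h = b.add("hn", 0.31, b.coords[ring[k]] + 1.01 * out)
            b.bond(ring[k], h)
        else:
            b.add_hydrogens(ring[k], 2, "hc", 0.05)
    mol = b.build()
    _, relaxed = _relax(mol, "core", seed)
    mol.coords = relaxed
    return Fixture(name="cyclic_dipeptide", seed=seed, mol=mol,
                   scheme_name="core", planted=relaxed,
                   extras={"ring_atoms": tuple(range(6))})


def _chiral_probe(seed: int) -> Fixture:
    b = _Builder()
    c = b.add("c3", 0.28, (0.0, 0.0, 0.0))
    dirs = tetrahedral_dirs([], 4)
    subs = [("h1", 0.07, 1.093), ("f", -0.17, 1.344),
            ("cl", -0.11, 1.786), ("br", -0.07, 1.944)]
    for d, (t, q, length) in zip(dirs, subs):
        a = b.add(t, q, length * d)
        b.bond(c, a)
    mol = b.build()
    _, relaxed = _relax(mol, "core", seed)
    mol.coords = relaxed
    return Fixture(name="chiral_probe", seed=seed, mol=mol,
                   scheme_name="core", planted=relaxed,
                   extras={"center": 0})


def _symmetric_ligand(seed: int) -> Fixture:
    """4-propylbenzoate anion (net charge -1)."""
    b = _Builder()
    ring = []
    ring_q = [0.06, -0.12, -0.12, 0.00, -0.12, -0.12]
    for k in range(6):
        ang = math.pi / 3.0 * k
        ring.append(b.add("ca", ring_q[k],
                          (1.398 * math.cos(ang), 1.398 * math.sin(ang),
                           0.0)))
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6])  # aromatic ring: typing (ca) carries aromaticity
    for k in (1, 2, 4, 5):
        out = _unit(np.array(b.coords[ring[k]]))
        h = b.add("ha", 0.13, b.coords[ring[k]] + 1.087 * out)
        b.bond(ring[k], h)
    # carboxylate on C1 (both C-O bonds single, equal charges: the two
    # oxygens stay topologically equivalent)
    cx = b.add("c", 0.70, b.coords[ring[0]] + np.array([1.487, 0.0, 0.0]))
    b.bond(ring[0], cx)
    for sign in (+1.0, -1.0):
        d = _unit(np.array([math.cos(math.radians(60)),
                            sign * math.sin(math.radians(60)), 0.0]))
        o = b.add("o", -0.80, b.coords[cx] + 1.25 * d,
                  formal=-1 if sign > 0 else 0)
        b.bond(cx, o)
    # propyl on C4
    prev = ring[3]
    chain = []
    for k, q in enumerate((-0.06, -0.08, -0.09)):
        step = np.array([-1.51, 0.0, 0.0]) if k == 0 else \
            np.array([-1.26, 0.0, 0.9 * (1 if k % 2 else -1)])
        chain.append(b.add("c3", q, b.coords[prev] + step))
        b.bond(prev, chain[-1])
        prev = chain[-1]
    b.add_hydrogens(chain[0], 2, "hc", 0.04)
    b.add_hydrogens(chain[1], 2, "hc", 0.04)
    b.add_hydrogens(chain[2], 3, "hc", 0.04)
    # land the total charge exactly on -1 via the unique carboxyl carbon
    residual = sum(b.charges) - (-1.0)
    b.charges[cx] -= residual
    mol = b.build()
    _, relaxed = _relax(mol, "core", seed)
    mol.coords = relaxed
    return Fixture(name="symmetric_ligand", seed=seed, mol=mol,
                   scheme_name="core", planted=relaxed,
                   extras={"carboxylate_oxygens": (cx + 1, cx + 2),
                           "carboxyl_carbon": cx,
                           "ring_atoms": tuple(ring)})


# ---------------------------------------------------------------------------
# cavity fixtures
# ---------------------------------------------------------------------------

PLATE_Z = 3.4
PLATE_SPACING = 2.46
# a snug cage: small plates above/below the ligand ring plus a barrel of
# three dense 12-atom wall rings slightly inside ring-H radius (2.49)
# plus the ha-ca vdW optimum (~3.37), so a centered ligand feels balanced
# compression from all sides and any lateral displacement is
# repulsion-dominated; only the in-plane orientation is soft, and the
# fixture's planted pose resolves it with an explicit rotation scan
WALL_RADIUS = 5.3
WALL_STAGGER = 0.0
RING_Z = 1.9
PLATE_RADIUS = 2.6


def _hex_lattice(max_radius: float) -> list[tuple[float, float]]:
    a1 = np.array([PLATE_SPACING, 0.0])
    a2 = np.array([PLATE_SPACING / 2.0,
                   PLATE_SPACING * math.sqrt(3.0) / 2.0])
    pts = []
    for i in range(-3, 4):
        for j in range(-3, 4):
            p = i * a1 + j * a2
            if np.linalg.norm(p) <= max_radius:
                pts.append((float(p[0]), float(p[1])))
    return sorted(pts)


def _slot_site(polar: bool) -> _Builder:
    """Two hydrophobic plates + a wall ring of fixed pseudo-atoms.

    The pseudo-atoms are bonded (plate lattice neighbors, the wall ring,
    the decoy star) so topological shells of the site fall into distinct
    symmetry sets and the interaction fingerprint can resolve it; bonded
    terms internal to the rigid site are excluded by the energy model.
    """
    b = _Builder()
    for z in (PLATE_Z, -PLATE_Z):
        plate = [b.add("ca", 0.0, (x, y, z), fixed=True, resname="CAV")
                 for x, y in _hex_lattice(PLATE_RADIUS)]
        for u in range(len(plate)):
            for v in range(u + 1, len(plate)):
                duv = np.linalg.norm(np.asarray(b.coords[plate[u]])
                                     - np.asarray(b.coords[plate[v]]))
                if duv < PLATE_SPACING + 0.1:
                    b.bond(plate[u], plate[v])
    for zr in (0.0, RING_Z, -RING_Z):
        wall = []
        for k in range(12):
            ang = math.pi / 6.0 * k
            rad = WALL_RADIUS + (WALL_STAGGER if k % 2 else 0.0)
            if polar and k == 0 and zr == 0.0:
                # wall acceptor on the inner shell (a hot-spot anchor)
                wall.append(b.add("o", -0.45, (rad, 0.0, 0.0), fixed=True,
                                  resname="CAV"))
            else:
                wall.append(b.add("ca", 0.0,
                                  (rad * math.cos(ang),
                                   rad * math.sin(ang), zr),
                                  fixed=True, resname="CAV"))
        for k in range(12):
            b.bond(wall[k], wall[(k + 1) % 12])
    if polar:
        # remote decoy patch: exaggerated negative charges on non-acceptor
        # carbons reward a shallow, fake-ionic pose under a low-dielectric
        # scheme without desolvation or contact bonuses
        decoy = [b.add("c3", q, xyz, fixed=True, resname="DEC")
                 for xyz, q in ((( 15.4, 0.0,  1.9), -0.85),
                                (( 15.4, 0.0, -1.9), -0.85),
                                (( 16.8, 0.0,  0.0),  0.00),
                                (( 15.4, 1.9,  0.0),  0.00),
                                (( 15.4, -1.9, 0.0),  0.00))]
        for idx in decoy[:2] + decoy[3:]:
            b.bond(idx, decoy[2])
    return b


def _benzene_mol() -> Molecule:
    b = _Builder()
    ring = []
    for k in range(6):
        ang = math.pi / 3.0 * k
        ring.append(b.add("ca", -0.115,
                          (1.398 * math.cos(ang), 1.398 * math.sin(ang),
                           0.0)))
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6])  # aromatic ring: typing (ca) carries aromaticity
    for k in range(6):
        out = _unit(np.array(b.coords[ring[k]]))
        h = b.add("ha", 0.115, b.coords[ring[k]] + 1.087 * out)
        b.bond(ring[k], h)
    return b.build()


def _phenol_mol() -> Molecule:
    """Phenol with the C-O bond along +x (ring center at the origin)."""
    b = _Builder()
    ring = []
    ring_q = [0.15, -0.13, -0.13, -0.13, -0.13, -0.13]
    for k in range(6):
        ang = math.pi / 3.0 * k
        ring.append(b.add("ca", ring_q[k],
                          (1.398 * math.cos(ang), 1.398 * math.sin(ang),
                           0.0)))
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6])  # aromatic ring: typing (ca) carries aromaticity
    for k in range(1, 6):
        out = _unit(np.array(b.coords[ring[k]]))
        h = b.add("ha", 0.13, b.coords[ring[k]] + 1.087 * out)
        b.bond(ring[k], h)
    o = b.add("oh", -0.55, b.coords[ring[0]] + np.array([1.362, 0.0, 0.0]))
    b.bond(ring[0], o)
    # O-H initially in-plane, tilted off +x so the torsion is well defined
    hd = _unit(np.array([math.cos(math.radians(71)),
                         math.sin(math.radians(71)), 0.0]))
    h = b.add("ho", 0.40, b.coords[o] + 0.974 * hd)
    b.bond(o, h)
    return b.build()


def _make_site(builder: _Builder) -> BindingSite:
    site_mol = builder.build()
    heavy = site_mol.heavy_atoms()
    center = site_mol.coords[heavy].mean(axis=0)
    site = BindingSite(mol=site_mol, center=center)
    site.hot_spots = auto_hot_spots(site)
    return site


def _place_ligand(complex_coords: np.ndarray, ligand_atoms: np.ndarray,
                  offset: np.ndarray) -> np.ndarray:
    out = complex_coords.copy()
    out[ligand_atoms] = out[ligand_atoms] + offset
    return out


def _cavity_hydrophobic(seed: int) -> Fixture:
    site = _make_site(_slot_site(polar=False))
    ligand = _benzene_mol()
    mol, lig = assemble_complex(site, ligand)
    ctx = SamplingContext(mol, get_scheme("fit"), hot_spots=site.hot_spots)
    rng = np.random.default_rng(seed)
    # planted pose: benzene centered in the slot, relaxed from the best
    # of a deterministic in-plane rotation scan (12-fold wall x 6-fold
    # ring: [0, 30) covers all distinct orientations)
    best_e, best_x = np.inf, None
    for deg in range(0, 30, 2):
        th = math.radians(deg)
        rot = np.array([[math.cos(th), -math.sin(th), 0.0],
                        [math.sin(th), math.cos(th), 0.0],
                        [0.0, 0.0, 1.0]])
        x0 = mol.coords.copy()
        x0[lig] = x0[lig] @ rot.T
        x = exhaustive_minimize(ctx, x0, rng, max_cycles=2)
        e = ctx.model.energy(x).total
        if e < best_e:
            best_e, best_x = e, x
    planted = exhaustive_minimize(ctx, best_x, rng, max_cycles=6)
    # unbiased start: ligand shifted well outside the slot
    start = _place_ligand(planted, lig, np.array([0.0, 0.0, 8.0]))
    mol.coords = planted
    return Fixture(name="cavity_hydrophobic", seed=seed, mol=mol,
                   scheme_name="fit", planted=planted, start=start,
                   ligand_atoms=lig, site_center=np.zeros(3),
                   hot_spots=site.hot_spots)


def _cavity_polar_decoy(seed: int) -> Fixture:
    site = _make_site(_slot_site(polar=True))
    ligand = _phenol_mol()
    mol, lig = assemble_complex(site, ligand)
    rng = np.random.default_rng(seed)
    # planted pose: phenol in the slot, O-H toward the wall acceptor,
    # relaxed under the fit scheme
    ctx_fit = SamplingContext(mol, get_scheme("fit"),
                              hot_spots=site.hot_spots)
    planted = exhaustive_minimize(ctx_fit, mol.coords, rng, max_cycles=6)
    # decoy pose: phenol at the charged surface patch, O-H pointing at the
    # fake ionic center, relaxed under the core scheme
    decoy0 = mol.coords.copy()
    decoy0[lig] = decoy0[lig] + np.array([11.1, 0.0, 0.0])
    ctx_core = SamplingContext(mol, get_scheme("core"),
                               hot_spots=site.hot_spots)
    decoy = exhaustive_minimize(ctx_core, decoy0, rng, max_cycles=6)
    start = _place_ligand(planted, lig, np.array([0.0, 0.0, 8.0]))
    mol.coords = planted
    return Fixture(name="cavity_polar_decoy", seed=seed, mol=mol,
                   scheme_name="fit", planted=planted, decoy=decoy,
                   start=start, ligand_atoms=lig,
                   site_center=np.zeros(3), hot_spots=site.hot_spots)


# ---------------------------------------------------------------------------
# rigged rescoring-scan oracle
# ---------------------------------------------------------------------------

def make_rigged_scan_set(planted: tuple[float, float, float]
                         = (0.01, 0.15, 0.15)) -> list[ScanComplex]:
    """Synthetic pose decompositions bracketing each class constant.

    Each complex holds two poses (native first, decoy second) whose
    energies are affine in exactly one hydrophobic class constant.  Per
    class, one complex makes the native pose win only above a threshold
    and one only below, so the full 10^3 scan is won by exactly one grid
    triplet -- the planted one.  Class order in the S matrices:
    (polarized, aromatic, aliphatic).
    """
    complexes = []

    def bracket(cls_index: int, low: float, high: float):
        s_native = np.zeros((2, 3, 3))
        s_native[0, cls_index, cls_index] = 10.0
        # native wins iff e0 - 10*K < 0  =>  K > low
        complexes.append(ScanComplex(
            name=f"class{cls_index}_lower",
            e_zero_k=np.array([10.0 * low, 0.0]),
            s_matrices=s_native,
            rmsd=np.array([0.5, 5.0])))
        s_decoy = np.zeros((2, 3, 3))
        s_decoy[1, cls_index, cls_index] = 10.0
        # decoy energy 10*high - 10*K: native wins iff K < high
        complexes.append(ScanComplex(
            name=f"class{cls_index}_upper",
            e_zero_k=np.array([0.0, 10.0 * high]),
            s_matrices=s_decoy,
            rmsd=np.array([0.5, 5.0])))

    # midpoints between each planted value and its grid neighbours
    midpoints = {0.01: (0.005, 0.0175), 0.15: (0.125, 0.175)}
    for cls_index, value in enumerate(planted):
        low, high = midpoints[value]
        bracket(cls_index, low, high)
    return complexes
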