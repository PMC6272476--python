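"""Pairwise interaction fingerprints, originality and symmetry-RMSD."""

import math

import numpy as np
import pytest

from molsample.chem import (Atom, Bond, Molecule, assign_interaction_roles,
                            build_symmetry_sets)
from molsample.fingerprints import (MIN_TOPO_SEPARATION, ORIGINALITY_MAX,
                                    build_layout, compute_pif, originality,
                                    pif_distance, symmetry_rmsd)
from molsample.forcefield import HYDROPHOBIC_RANGE, contact_switch


def _methane_cluster(carbon_positions):
    """Disconnected methanes; the carbons form one hydrophobe symmetry set."""
    atoms, bonds, coords = [], [], []
    for c in carbon_positions:
        base = len(atoms)
        atoms.append(Atom(index=base, element="C", ff_type="c3"))
        coords.append(c)
        for k, off in enumerate(((0.6, 0.6, 0.6), (-0.6, -0.6, 0.6),
                                 (0.6, -0.6, -0.6), (-0.6, 0.6, -0.6))):
            atoms.append(Atom(index=base + 1 + k, element="H", ff_type="hc"))
            bonds.append(Bond(i=base, j=base + 1 + k, order=1))
            coords.append(tuple(np.add(c, off)))
    m = Molecule(atoms, bonds, np.asarray(coords, dtype=float))
    return assign_interaction_roles(m)


def _hydrophobic_d_for(c):
    """Distance at which the unit-amplitude hydrophobic switch equals c."""
    lo2, hi2 = HYDROPHOBIC_RANGE[0] ** 2, HYDROPHOBIC_RANGE[1] ** 2
    t = math.acos(2.0 * c - 1.0) / math.pi
    return math.sqrt(lo2 + t * (hi2 - lo2))


def test_single_member_pair_equals_c():
    d = _hydrophobic_d_for(0.7)
    mol = _methane_cluster([(0, 0, 0), (d, 0, 0)])
    layout = build_layout(mol)
    assert layout.n_features == 1
    pif = compute_pif(layout, mol.coords)
    # self-weighted average of one contact: 0.49 / 0.7 = 0.7
    assert pif[0] == pytest.approx(0.7, abs=1e-9)


def test_two_member_pairs_biased_average():
    d1 = _hydrophobic_d_for(0.6)
    d2 = _hydrophobic_d_for(0.8)
    # triangle: carbon 0 at origin sees 1 at d1 and 2 at d2; leg 1-2 is
    # longer than the switching range, so its contact strength is 0
    d12 = 6.0
    x = (d1 * d1 + d2 * d2 - d12 * d12) / (2.0 * d1)
    y = math.sqrt(d2 * d2 - x * x)
    mol = _methane_cluster([(0, 0, 0), (d1, 0, 0), (x, y, 0)])
    layout = build_layout(mol)
    assert layout.n_features == 1
    pif = compute_pif(layout, mol.coords)
    assert pif[0] == pytest.approx((0.36 + 0.64) / 1.4, abs=1e-9)


def test_all_zero_contacts_give_zero():
    mol = _methane_cluster([(0, 0, 0), (40, 0, 0)])
    layout = build_layout(mol)
    assert compute_pif(layout, mol.coords)[0] == 0.0


def test_eq2_oracle_on_small_layouts():
    # per-feature value recomputed by hand from the member-pair switches;
    # biased average lies in [min C, max C] and is >= the plain mean
    d1 = _hydrophobic_d_for(0.35)
    d2 = _hydrophobic_d_for(0.9)
    x = (d1 * d1 + d2 * d2 - 36.0) / (2.0 * d1)
    y = math.sqrt(d2 * d2 - x * x)
    for carbons in ([(0, 0, 0), (_hydrophobic_d_for(0.5), 0, 0)],
                    [(0, 0, 0), (d1, 0, 0), (x, y, 0)]):
        mol = _methane_cluster(carbons)
        layout = build_layout(mol)
        assert len(layout.pair_i) <= 4
        pif = compute_pif(layout, mol.coords)
        dvec = mol.coords[layout.pair_i] - mol.coords[layout.pair_j]
        c = contact_switch(np.einsum("ij,ij->i", dvec, dvec),
                           layout.dmin2, layout.dmax2)
        assert pif[0] == pytest.approx(np.sum(c * c) / np.sum(c), abs=1e-12)
        assert c.min() - 1e-12 <= pif[0] <= c.max() + 1e-12
        assert pif[0] >= np.mean(c) - 1e-12


def test_ring_pairs_topologically_too_close_excluded():
    from molsample.fixtures import _benzene_mol
    mol = _benzene_mol()
    # every set pair inside the ring has T <= 5
    layout = build_layout(mol)
    assert layout.n_features == 0
    assert len(compute_pif(layout, mol.coords)) == 0


def test_donor_donor_and_acceptor_acceptor_excluded():
    # two remote waters: the merged donor set may not pair with itself, the
    # merged acceptor set may not pair with itself, and the donor-acceptor
    # pair is vetoed by the conservative (min over members) T = 1
    atoms, bonds, coords = [], [], []
    for ox in (0.0, 30.0):
        b = len(atoms)
        atoms.append(Atom(index=b, element="O", ff_type="oh"))
        atoms.append(Atom(index=b + 1, element="H", ff_type="ho"))
        atoms.append(Atom(index=b + 2, element="H", ff_type="ho"))
        bonds += [Bond(i=b, j=b + 1, order=1), Bond(i=b, j=b + 2, order=1)]
        coords += [(ox, 0, 0), (ox + 0.96, 0, 0), (ox - 0.24, 0.93, 0)]
    mol = assign_interaction_roles(Molecule(atoms, bonds,
                                            np.asarray(coords, float)))
    sets = build_symmetry_sets(mol, typed_only=True)
    assert {s.role for s in sets} == {"donor_H", "acceptor"}
    assert build_layout(mol).n_features == 0


def test_fully_fixed_pair_excluded():
    d = _hydrophobic_d_for(0.5)
    mol = _methane_cluster([(0, 0, 0), (d, 0, 0)])
    mol.set_fixed(range(mol.n_atoms))
    assert build_layout(mol).n_features == 0
    # one free atom on either side is enough
    mol.set_fixed(range(5, mol.n_atoms), fixed=False)
    assert build_layout(mol).n_features == 1


def test_layout_is_geometry_independent_and_deterministic():
    a = _methane_cluster([(0, 0, 0), (5.0, 0, 0)])
    b = _methane_cluster([(0, 0, 0), (17.0, 3.0, 1.0)])
    la, lb = build_layout(a), build_layout(b)
    assert la.roles == lb.roles
    assert [p[0].members for p in la.set_pairs] == \
        [p[0].members for p in lb.set_pairs]
    assert np.array_equal(la.pair_i, lb.pair_i)
    assert la.describe() == lb.describe()


def _with_lone_donor(fx, position):
    """Copy of a fixture molecule plus a disconnected polar hydrogen."""
    mol = fx.mol
    atoms = [Atom(index=a.index, element=a.element, ff_type=a.ff_type,
                  charge=a.charge) for a in mol.atoms]
    atoms.append(Atom(index=mol.n_atoms, element="H", ff_type="hn",
                      charge=0.3))
    bonds = [Bond(i=b.i, j=b.j, order=b.order) for b in mol.bonds]
    coords = np.vstack([mol.coords, np.asarray(position, float)])
    return assign_interaction_roles(Molecule(atoms, bonds, coords))


def test_carboxylate_flip_leaves_pif_invariant(symmetric_fx):
    o1, o2 = symmetric_fx.extras["carboxylate_oxygens"]
    # a lone donor near one oxygen makes the H-bond feature non-trivial
    probe = symmetric_fx.mol.coords[o1] + np.array([2.0, 0.0, 0.0])
    mol = _with_lone_donor(symmetric_fx, probe)
    layout = build_layout(mol)
    donor = mol.n_atoms - 1
    hb = [k for k, (sa, sb) in enumerate(layout.set_pairs)
          if donor in sa.members + sb.members
          and {sa.role, sb.role} == {"donor_H", "acceptor"}
          and (o1 in sa.members + sb.members)]
    assert hb, "expected a donor vs carboxylate-oxygen feature"
    base = compute_pif(layout, mol.coords)
    assert base[hb[0]] > 0.0
    flipped = mol.coords.copy()
    flipped[[o1, o2]] = flipped[[o2, o1]]
    # individual donor-oxygen distances change ...
    assert not np.isclose(np.linalg.norm(flipped[o1] - flipped[donor]),
                          np.linalg.norm(mol.coords[o1] - mol.coords[donor]))
    # ... but no fingerprint element moves by more than 1e-9
    assert np.max(np.abs(compute_pif(layout, flipped) - base)) < 1e-9


def test_pif_distance_examples_and_axioms(rng):
    assert pif_distance(np.zeros(4), np.zeros(4)) == 0.0
    assert pif_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0
    assert pif_distance(np.array([], dtype=float),
                        np.array([], dtype=float)) == 0.0
    with pytest.raises(ValueError):
        pif_distance(np.zeros(3), np.zeros(4))
    for _ in range(50):
        a, b, c = rng.uniform(size=(3, 5))
        assert pif_distance(a, b) == pytest.approx(pif_distance(b, a))
        assert 0.0 <= pif_distance(a, b) <= 1.0
        assert pif_distance(a, c) <= \
            pif_distance(a, b) + pif_distance(b, c) + 1e-12
        assert pif_distance(a, a) == 0.0


def test_originality_examples():
    pifs = [np.array([0.2, 0.8]), np.array([0.2, 0.8]),
            np.array([0.204, 0.8])]
    energies = [-5.0, -4.0, -4.5]
    # duplicate of a fitter member
    assert originality(energies[1], pifs[1], energies, pifs) == 0.0
    # fittest member: sentinel maximum
    assert originality(energies[0], pifs[0], energies, pifs) \
        == ORIGINALITY_MAX
    # min delta to the strictly fitter members only
    w = originality(energies[2], pifs[2], energies, pifs)
    assert w == pytest.approx(0.004 / 2)
    assert w < 0.01  # redundant at minfpdiff = 0.01
    # population of one
    assert originality(-1.0, pifs[0], [-1.0], [pifs[0]]) == ORIGINALITY_MAX
    # empty fingerprint carries no redundancy evidence
    assert originality(-1.0, np.array([]), [-2.0, -1.0],
                       [np.array([]), np.array([])]) == ORIGINALITY_MAX


def test_symmetry_rmsd_oxygen_swap(symmetric_fx):
    mol = symmetric_fx.mol
    o1, o2 = symmetric_fx.extras["carboxylate_oxygens"]
    swapped = mol.coords.copy()
    swapped[[o1, o2]] = swapped[[o2, o1]]
    heavy = mol.heavy_atoms()
    plain = math.sqrt(np.mean(np.sum(
        (mol.coords[heavy] - swapped[heavy]) ** 2, axis=1)))
    assert plain > 0.1
    assert symmetry_rmsd(mol, mol.coords, swapped) < 1e-12
    assert symmetry_rmsd(mol, mol.coords, swapped, brute_force=True) < 1e-12


def test_symmetry_rmsd_asymmetric_equals_plain(rng):
    mol = assign_interaction_roles(Molecule(
        [Atom(index=0, element="C", ff_type="c3"),
         Atom(index=1, element="C", ff_type="c3"),
         Atom(index=2, element="O", ff_type="oh")],
        [Bond(i=0, j=1, order=1), Bond(i=1, j=2, order=1)],
        np.array([[0.0, 0, 0], [1.5, 0, 0], [2.2, 1.1, 0]])))
    other = mol.coords + rng.normal(scale=0.3, size=mol.coords.shape)
    plain = math.sqrt(np.mean(np.sum((mol.coords - other) ** 2, axis=1)))
    assert symmetry_rmsd(mol, mol.coords, other) == pytest.approx(plain)


def test_symmetry_rmsd_benzene_rotation():
    from molsample.fixtures import _benzene_mol
    mol = _benzene_mol()
    center = mol.coords.mean(axis=0)
    th = math.pi / 3.0
    rot = np.array([[math.cos(th), -math.sin(th), 0.0],
                    [math.sin(th), math.cos(th), 0.0],
                    [0.0, 0.0, 1.0]])
    rotated = (mol.coords - center) @ rot.T + center
    heavy = mol.heavy_atoms()
    plain = math.sqrt(np.mean(np.sum(
        (mol.coords[heavy] - rotated[heavy]) ** 2, axis=1)))
    assert plain > 1.0
    assert symmetry_rmsd(mol, mol.coords, rotated) < 1e-9
    assert symmetry_rmsd(mol, mol.coords, rotated, brute_force=True) < 1e-9


def test_assignment_matches_brute_force(symmetric_fx, rng):
    mol = symmetric_fx.mol
    for _ in range(5):
        other = mol.coords + rng.normal(scale=0.5, size=mol.coords.shape)
        fast = symmetry_rmsd(mol, mol.coords, other)
        slow = symmetry_rmsd(mol, mol.coords, other, brute_force=True)
        assert fast == pytest.approx(slow, abs=1e-9)


def test_symmetry_rmsd_subset_and_empty(cavity_hydro_fx):
    fx = cavity_hydro_fx
    shifted = fx.mol.coords.copy()
    lig = list(fx.ligand_atoms)
    shifted[lig] += np.array([1.0, 0.0, 0.0])
    r = symmetry_rmsd(fx.mol, fx.mol.coords, shifted, atom_subset=lig)
    assert r == pytest.approx(1.0, abs=1e-9)
    assert symmetry_rmsd(fx.mol, fx.mol.coords, shifted, atom_subset=[]) \
        == 0.0
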