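"""Energy terms, gradients, cutoffs, chirality."""

import math

import numpy as np
import pytest

from molsample.chem import Atom, Bond, Molecule, assign_interaction_roles
from molsample.forcefield import (COULOMB_CONST, D2_OFFSET, MAXCUT,
                                  ChiralityReference, EnergyModel,
                                  TorsionRestraint, assign_vdw_radii,
                                  build_chirality_references,
                                  chirality_penalty, contact_pair,
                                  contact_switch, coulomb_pair,
                                  desolvation_pair, dihedral_angle,
                                  energy_total, pair_cutoff_scan,
                                  signed_projection, termination_weight,
                                  vdw_pair)
from molsample.params import get_scheme

FIT = get_scheme("fit")
CORE = get_scheme("core")
PRELIM = get_scheme("preliminary")


def _pair_system(t1, t2, q1, q2, d):
    """Two disjoint atoms (topological distance 999) at distance d."""
    atoms = [Atom(index=0, element=t1[0].upper(), ff_type=t1, charge=q1),
             Atom(index=1, element=t2[0].upper(), ff_type=t2, charge=q2)]
    m = Molecule(atoms, [], np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
    assign_interaction_roles(m)
    assign_vdw_radii(m)
    return m


# ---------------------------------------------------------------------------
# pure pairwise formulas (the printed worked examples)
# ---------------------------------------------------------------------------

def test_desolvation_examples():
    assert desolvation_pair(0.1, 0.1, 2.0, FIT) == 0.0  # below minq 0.125
    assert desolvation_pair(0.4, 0.0, 2.0, PRELIM) == \
        pytest.approx(0.001, abs=1e-9)
    assert desolvation_pair(0.4, 0.0, 2.0, FIT, is_hb_pair=True) == \
        pytest.approx(0.0001, abs=1e-9)
    with pytest.raises(ValueError):
        desolvation_pair(0.4, 0.0, 0.0, FIT)


def test_coulomb_examples():
    assert coulomb_pair(0.5, 0.5, 3.0, PRELIM) == \
        pytest.approx(332 * 0.25 / 36, abs=1e-9)
    assert coulomb_pair(0.0, 0.7, 2.0, FIT) == 0.0
    assert coulomb_pair(1.0, -1.0, 1.0, CORE) == pytest.approx(-166.0,
                                                               abs=1e-9)


def test_contact_examples():
    ca = Atom(index=0, element="C", ff_type="ca", role="hydrophobe",
              hydro_class="aromatic")
    cb = Atom(index=1, element="C", ff_type="ca", role="hydrophobe",
              hydro_class="aromatic")
    assert contact_pair(ca, cb, 4.0, FIT) == pytest.approx(-0.15, abs=1e-9)
    assert contact_pair(ca, cb, 5.6, FIT) == pytest.approx(0.0, abs=1e-9)
    d_mid = math.sqrt((4.5 ** 2 + 5.5 ** 2) / 2.0)
    assert contact_pair(ca, cb, d_mid, FIT) == \
        pytest.approx(-0.15 * 0.5, abs=1e-9)
    none_atom = Atom(index=2, element="N", ff_type="x", role="none")
    with pytest.raises(ValueError):
        contact_pair(ca, none_atom, 4.0, FIT)


def test_contact_switch_is_c1_in_d2():
    # continuous and once-differentiable across both switching edges
    for edge in (4.5 ** 2, 5.5 ** 2):
        h = 1e-7
        lo = contact_switch(edge - h, 4.5 ** 2, 5.5 ** 2)
        hi = contact_switch(edge + h, 4.5 ** 2, 5.5 ** 2)
        assert abs(lo - hi) < 1e-6
        dlo = (contact_switch(edge, 4.5 ** 2, 5.5 ** 2) - lo) / h
        dhi = (hi - contact_switch(edge, 4.5 ** 2, 5.5 ** 2)) / h
        assert abs(dlo - dhi) < 1e-4  # derivative is 0 at both edges


def test_vdw_examples():
    A, B = 5000.0, 30.0
    d_min = (2.0 * A / B) ** (1.0 / 6.0)
    assert vdw_pair(A, B, d_min, CORE) == \
        pytest.approx(-B * B / (4.0 * A), abs=1e-9)
    plain = vdw_pair(A, B, 3.0, CORE)
    assert vdw_pair(A, B, 3.0, CORE, vicinal=True) == \
        pytest.approx(0.5 * plain, abs=1e-12)
    assert abs(vdw_pair(A, B, 1e4, CORE)) < 1e-9


def test_termination_weight_examples():
    assert termination_weight(0.0, 8.0) == pytest.approx(1.0, abs=1e-12)
    assert termination_weight(8.0, 8.0) == pytest.approx(0.0, abs=1e-12)
    assert termination_weight(9.0, 8.0) == 0.0
    # d(omega)/dd vanishes at the cutoff (smooth termination)
    h = 1e-6
    deriv = (termination_weight(8.0, 8.0)
             - termination_weight(8.0 - h, 8.0)) / h
    assert abs(deriv) < 1e-4
    with pytest.raises(ValueError):
        termination_weight(1.0, 0.0)


# ---------------------------------------------------------------------------
# pair cutoffs
# ---------------------------------------------------------------------------

def test_cutoff_negligible_pair_collapses():
    cut = pair_cutoff_scan(lambda d: 0.0)
    assert cut == pytest.approx(0.1)


def test_cutoff_strong_coulomb_10_to_12():
    # a pair with a strong Coulomb contribution terminates in 10-12 A
    cut = pair_cutoff_scan(
        lambda d: coulomb_pair(0.25, 0.06, d, FIT))
    assert 10.0 <= cut <= 12.0
    # literal unit charges saturate the 15 A maximum
    assert pair_cutoff_scan(lambda d: coulomb_pair(1.0, 1.0, d, FIT)) == \
        pytest.approx(MAXCUT)


def test_cutoff_pure_vdw_about_6():
    rij = 2 * 1.908
    eij = 0.1094
    A, B = eij * rij ** 12, 2 * eij * rij ** 6
    cut = pair_cutoff_scan(lambda d: vdw_pair(A, B, d, CORE))
    assert 5.0 <= cut <= 7.0


def test_energy_continuous_across_pair_cutoff():
    # scan a neutral polar pair's energy through its compiled cutoff
    m = _pair_system("c3", "c3", 0.3, -0.3, 5.0)
    model = EnergyModel(m, FIT)
    cut = math.sqrt(float(model.pairs["cut2"][0]))
    x = m.coords.copy()

    def e_at(d):
        x[1, 0] = d
        return model.energy(x).total

    eps = 1e-7
    assert abs(e_at(cut - eps) - e_at(cut + eps)) < 1e-8
    assert e_at(cut + 0.5) == pytest.approx(0.0, abs=1e-12)
    # and it is continuous on a fine grid straddling the cutoff
    ds = np.linspace(cut - 0.05, cut + 0.05, 201)
    es = np.array([e_at(d) for d in ds])
    assert np.max(np.abs(np.diff(es))) < 1e-4


# ---------------------------------------------------------------------------
# chirality / out-of-plane
# ---------------------------------------------------------------------------

def test_chirality_penalty_examples(chiral_fx):
    mol = chiral_fx.mol
    refs = build_chirality_references(mol)
    assert len(refs) == 1 and refs[0].kind == "tetrahedral"
    assert chirality_penalty(mol.coords, refs[0]) == 0.0
    # mirrored geometry with |p| forced to 0.5 -> k_chir * 0.5 = 50
    ref = refs[0]
    mirrored = mol.coords.copy()
    mirrored[:, 2] *= -1.0
    p = signed_projection(mirrored, ref.center, ref.subs)
    assert p * ref.p0 < 0
    scaled = ChiralityReference(center=ref.center, subs=ref.subs,
                                kind="tetrahedral", p0=ref.p0)
    # rescale so |p| = 0.5 exactly, moving only the center atom
    shift = (0.5 - abs(p)) * np.sign(p)
    normal_dir = _unit_normal(mirrored, ref)
    mirrored[ref.center] += shift * normal_dir
    p2 = signed_projection(mirrored, ref.center, ref.subs)
    assert abs(abs(p2) - 0.5) < 1e-9
    assert chirality_penalty(mirrored, scaled) == pytest.approx(50.0,
                                                                abs=1e-6)


def _unit_normal(coords, ref):
    l, h, hh = ref.subs[-3], ref.subs[-2], ref.subs[-1]
    n = np.cross(coords[hh] - coords[l], coords[h] - coords[l])
    return n / np.linalg.norm(n)


def test_trigonal_oop_threshold(dipeptide_fx):
    mol = dipeptide_fx.mol
    refs = [r for r in build_chirality_references(mol)
            if r.kind == "trigonal"]
    assert refs  # carbonyl carbons and amide nitrogens
    ref = refs[0]
    x = mol.coords.copy()
    n = _unit_normal(x, ref)
    base = signed_projection(x, ref.center, ref.subs)
    x[ref.center] += (0.005 - base) * n
    assert abs(signed_projection(x, ref.center, ref.subs) - 0.005) < 1e-9
    assert chirality_penalty(x, ref) == 0.0
    x[ref.center] += 0.05 * n
    p = signed_projection(x, ref.center, ref.subs)
    assert chirality_penalty(x, ref) == \
        pytest.approx(200.0 * (abs(p) - 0.01), abs=1e-9)


def test_chirality_energy_in_model(chiral_fx):
    mol = chiral_fx.mol
    model = EnergyModel(mol, CORE)
    assert model.energy(mol.coords).terms["chirality"] == 0.0
    mirrored = mol.coords.copy()
    mirrored[:, 0] *= -1.0
    assert model.energy(mirrored).terms["chirality"] > 0.0


# ---------------------------------------------------------------------------
# whole-model properties
# ---------------------------------------------------------------------------

def test_report_terms_sum_to_total(symmetric_fx):
    rep = energy_total(symmetric_fx.mol, symmetric_fx.mol.coords, FIT)
    assert rep.total == pytest.approx(sum(rep.terms.values()), abs=1e-9)


def test_core_scheme_has_no_desolv_or_contact(symmetric_fx):
    rep = energy_total(symmetric_fx.mol, symmetric_fx.mol.coords, CORE)
    assert rep.terms["desolv"] == 0.0
    assert rep.terms["contact"] == 0.0


def test_rigid_translation_rotation_invariance(symmetric_fx):
    mol = symmetric_fx.mol
    model = EnergyModel(mol, FIT)
    e0 = model.energy(mol.coords).total
    th = 0.7
    R = np.array([[math.cos(th), -math.sin(th), 0.0],
                  [math.sin(th), math.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    moved = mol.coords @ R.T + np.array([3.0, -2.0, 1.0])
    assert model.energy(moved).total == pytest.approx(e0, abs=1e-8)


def test_gradient_matches_finite_differences(butane_fx, rng):
    mol = butane_fx.mol
    model = EnergyModel(mol, CORE)
    x = mol.coords + rng.normal(scale=0.05, size=mol.coords.shape)
    _, g = model.energy_and_gradient(x)
    h = 1e-5
    fd = np.zeros_like(g)
    for i in range(mol.n_atoms):
        for k in range(3):
            xp = x.copy(); xp[i, k] += h
            xm = x.copy(); xm[i, k] -= h
            fd[i, k] = (model.energy(xp).total
                        - model.energy(xm).total) / (2 * h)
    denom = max(1.0, float(np.linalg.norm(fd)))
    assert np.linalg.norm(fd - g) / denom < 1e-5


def test_fixed_atoms_get_zero_gradient(cavity_hydro_fx):
    fx = cavity_hydro_fx
    model = EnergyModel(fx.mol, FIT)
    _, g = model.energy_and_gradient(fx.planted)
    assert np.all(g[fx.mol.fixed_mask] == 0.0)


def test_rigid_receptor_excludes_internal_site_terms(cavity_hydro_fx):
    mol = cavity_hydro_fx.mol
    model = EnergyModel(mol, FIT)
    fixed = mol.fixed_mask
    ii, jj = model.pairs["i"], model.pairs["j"]
    assert not np.any(fixed[ii] & fixed[jj])
    assert not np.any(fixed[model.b_i] & fixed[model.b_j])
    # the constant-term bucket is empty under this convention
    assert all(v == 0.0 for v in model._const_terms.values())


def test_missing_parameters_enumerated():
    atoms = [Atom(index=0, element="X", ff_type="xx")]
    m = Molecule(atoms, [], np.zeros((1, 3)))
    with pytest.raises(KeyError, match="xx"):
        EnergyModel(m, CORE)


def test_torsion_restraint_applies_and_removes(butane_fx):
    mol = butane_fx.mol
    model = EnergyModel(mol, CORE)
    quad = butane_fx.extras["torsion_quad"]
    phi = dihedral_angle(mol.coords, *quad)
    base = model.energy(mol.coords).total
    r = TorsionRestraint(quad=quad, k=10.0, target=phi + 0.5)
    model.torsion_restraints.append(r)
    with_r = model.energy(mol.coords)
    assert with_r.terms["restraint"] == pytest.approx(10.0 * 0.25, abs=1e-9)
    model.torsion_restraints.remove(r)
    assert model.energy(mol.coords).total == pytest.approx(base, abs=1e-12)


def test_d2_offset_keeps_overlap_finite():
    m = _pair_system("c3", "c3", 0.5, -0.5, 1e-6)
    model = EnergyModel(m, FIT)
    e = model.energy(m.coords).total
    assert np.isfinite(e)
    # near contact the 1/d^n terms are governed by the d2offset floor, so
    # the energy saturates instead of diverging as d -> 0
    x = m.coords.copy()
    x[1, 0] = 1e-9
    assert model.energy(x).total == pytest.approx(e, rel=1e-6)
    assert D2_OFFSET == 0.01


def test_coulomb_const_value():
    assert COULOMB_CONST == 332.0
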