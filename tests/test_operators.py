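"""Genetic and local-search operators."""

import math

import numpy as np
import pytest

from molsample.chem import Atom, Bond, Molecule, assign_interaction_roles
from molsample.operators import (PROBE_RADIUS, OperatorBudget,
                                 SamplingContext, accessible_point, cross,
                                 dock_c, dock_e, draw_contact_axis,
                                 exhaustive_minimize, fragment_recombination,
                                 local_opt, mutate, place_on_axis,
                                 random_init, uniform_torsional_crossover)
from molsample.params import get_scheme


@pytest.fixture(scope="module")
def butane_ctx(butane_fx):
    return SamplingContext(butane_fx.mol, get_scheme("core"))


@pytest.fixture(scope="module")
def cavity_ctx(cavity_hydro_fx):
    fx = cavity_hydro_fx
    return SamplingContext(fx.mol, get_scheme("fit"),
                           hot_spots=fx.hot_spots)


def _methane(offset=(0.0, 0.0, 0.0)):
    atoms = [Atom(index=0, element="C", ff_type="c3", charge=-0.4)]
    bonds, coords = [], [offset]
    for k, off in enumerate(((0.63, 0.63, 0.63), (-0.63, -0.63, 0.63),
                             (0.63, -0.63, -0.63), (-0.63, 0.63, -0.63))):
        atoms.append(Atom(index=k + 1, element="H", ff_type="hc",
                          charge=0.1))
        bonds.append(Bond(i=0, j=k + 1, order=1))
        coords.append(tuple(np.add(offset, off)))
    return assign_interaction_roles(
        Molecule(atoms, bonds, np.asarray(coords, float)))


def test_operator_budget_defaults():
    b = OperatorBudget()
    assert b.pair_pick_trials == 50
    assert b.dockc_max_attempts == 50
    assert b.docke_patience == 20
    assert b.lo_steps == (20, 50)
    assert b.docke_probability == 0.30
    assert b.fragment_recomb_probability == 0.80


def test_set_torsion_round_trip(butane_ctx, butane_fx, rng):
    ctx = butane_ctx
    axis = next(t for t in ctx.torsion_axes if set(t.bond) == {1, 2})
    coords = butane_fx.mol.coords.copy()
    for target in (-2.5, -1.0, 0.3, 1.7, 3.0):
        ctx.set_torsion(coords, axis, target)
        got = ctx.get_torsion(coords, axis)
        assert math.remainder(got - target, 2 * math.pi) \
            == pytest.approx(0.0, abs=1e-6)


def test_local_opt_relaxes_stretched_bond(rng):
    mol = _methane()
    ctx = SamplingContext(mol, get_scheme("core"))
    r0 = ctx.model.params.bond_param("c3", "hc")[1]
    coords = mol.coords.copy()
    coords[1] = coords[0] + 2.0 * (coords[1] - coords[0]) \
        / np.linalg.norm(coords[1] - coords[0])
    e_in = ctx.model.energy(coords).total
    out = local_opt(ctx, coords, rng, steps=50)
    e_out = ctx.model.energy(out).total
    assert e_out < e_in
    assert abs(np.linalg.norm(out[1] - out[0]) - r0) < \
        abs(np.linalg.norm(coords[1] - coords[0]) - r0)


def test_local_opt_monotone_and_stationary(butane_ctx, butane_fx, rng):
    ctx = butane_ctx
    x = butane_fx.mol.coords + rng.normal(scale=0.05, size=(14, 3))
    e_in = ctx.model.energy(x).total
    out = local_opt(ctx, x, rng)
    assert ctx.model.energy(out).total <= e_in + 1e-6


def test_local_opt_stationary_point_unchanged(rng):
    mol = assign_interaction_roles(Molecule(
        [Atom(index=0, element="C", ff_type="c3"),
         Atom(index=1, element="C", ff_type="c3")],
        [Bond(i=0, j=1, order=1)],
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])))
    ctx = SamplingContext(mol, get_scheme("core"))
    r0 = ctx.model.params.bond_param("c3", "c3")[1]
    at_min = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    out = local_opt(ctx, at_min, rng)
    assert np.max(np.abs(out - at_min)) < 1e-6


def test_local_opt_fixed_atoms_bitwise_unchanged(cavity_hydro_fx, rng):
    fx = cavity_hydro_fx
    ctx = SamplingContext(fx.mol, get_scheme("fit"), hot_spots=fx.hot_spots)
    fixed = np.flatnonzero(fx.mol.fixed_mask)
    assert len(fixed) > 0
    out = local_opt(ctx, fx.start.copy(), rng)
    assert np.array_equal(out[fixed], fx.start[fixed])


def test_exhaustive_minimize_quadratic_and_deterministic():
    mol = _methane()
    ctx = SamplingContext(mol, get_scheme("core"))
    r0 = ctx.model.params.bond_param("c3", "hc")[1]
    start = mol.coords * 1.3
    a = exhaustive_minimize(ctx, start, np.random.default_rng(5))
    b = exhaustive_minimize(ctx, start, np.random.default_rng(5))
    assert np.array_equal(a, b)
    for h in (1, 2, 3, 4):
        assert np.linalg.norm(a[h] - a[0]) == pytest.approx(r0, abs=2e-3)


def test_accessible_point_sphere_constraint(rng):
    mol = _methane()
    lone = assign_interaction_roles(Molecule(
        [Atom(index=0, element="C", ff_type="c3")], [],
        np.zeros((1, 3))))
    p = accessible_point(0, lone, lone.coords, rng)
    r = lone.atoms[0].vdw_radius + PROBE_RADIUS
    assert np.linalg.norm(p - lone.coords[0]) == pytest.approx(r, abs=1e-9)
    # carbon buried under its own hydrogens at punishing probe radius
    assert accessible_point(0, mol, mol.coords, rng, probe=3.0) is None


def test_dock_c_clash_free_input_untouched(butane_ctx, butane_fx, rng):
    coords = butane_fx.mol.coords.copy()
    out, ok = dock_c(butane_ctx, coords, [0, 4, 5, 6],
                     coords[1], coords[0] - coords[1], rng)
    assert ok and np.array_equal(out, coords)


def test_dock_c_unresolvable_clash_flagged(rng):
    mol = assign_interaction_roles(Molecule(
        [Atom(index=0, element="C", ff_type="c3"),
         Atom(index=1, element="C", ff_type="c3")], [],
        np.array([[0.0, 0, 0], [0.5, 0, 0]])))
    ctx = SamplingContext(mol, get_scheme("core"))
    # rotating atom 1 about a line through itself can never relieve overlap
    out, ok = dock_c(ctx, mol.coords.copy(), [1], mol.coords[1],
                     np.array([0.0, 0.0, 1.0]), rng)
    assert not ok
    assert ctx.clash_score(out, [1]) > 0


def test_dock_e_patience_and_monotonicity(rng):
    mol = _methane()
    far = _methane((40.0, 0.0, 0.0))
    atoms = [Atom(index=i, element=a.element, ff_type=a.ff_type,
                  charge=a.charge)
             for i, a in enumerate(mol.atoms + far.atoms)]
    bonds = [Bond(i=b.i, j=b.j, order=b.order) for b in mol.bonds] + \
        [Bond(i=b.i + 5, j=b.j + 5, order=b.order) for b in far.bonds]
    m = assign_interaction_roles(
        Molecule(atoms, bonds, np.vstack([mol.coords, far.coords])))
    ctx = SamplingContext(m, get_scheme("core"))
    calls = []
    orig = ctx.model.energy

    def counting(x):
        calls.append(1)
        return orig(x)

    ctx.model.energy = counting
    e0 = orig(m.coords).total
    out = dock_e(ctx, m.coords.copy(), list(range(5, 10)),
                 m.coords[5], np.array([0.0, 0.0, 1.0]), rng)
    ctx.model.energy = orig
    # beyond every cutoff the energy is flat: initial evaluation plus
    # exactly 20 non-improving attempts, then stop
    assert len(calls) == 1 + ctx.budget.docke_patience
    assert orig(out).total <= e0 + 1e-12


def test_bound_recombination_restores_cut_bond(butane_ctx, butane_fx):
    ctx = butane_ctx
    frag = next(f for f in ctx.fragments if set(f.pivot_bond) == {1, 2})
    p1 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(1))
    p2 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(2))
    child = fragment_recombination(ctx, p1, p2, np.random.default_rng(3),
                                   frag=frag, do_lo=False)
    r0 = ctx.model.params.bond_param("c3", "c3")[1]
    fa, fb = frag.pivot_bond
    assert np.linalg.norm(child[fa] - child[fb]) \
        == pytest.approx(r0, abs=1e-3)
    # complement keeps parent1's geometry
    comp = sorted(frag.complement)
    assert np.array_equal(child[comp], p1[comp])


def test_loose_placement_geometry(cavity_ctx, cavity_hydro_fx):
    ctx = cavity_ctx
    fx = cavity_hydro_fx
    frag = next(f for f in ctx.fragments if f.kind == "loose")
    axis = None
    for seed in range(10):
        axis = draw_contact_axis(ctx, fx.start, frag, fx.start,
                                 np.random.default_rng(seed))
        if axis is not None:
            break
    assert axis is not None
    a, ap = axis.site_atom, axis.ligand_atom
    r_a = fx.mol.atoms[a].vdw_radius + PROBE_RADIUS
    r_ap = fx.mol.atoms[ap].vdw_radius + PROBE_RADIUS
    assert np.linalg.norm(axis.site_point - fx.start[a]) \
        == pytest.approx(r_a, abs=1e-9)
    out = place_on_axis(ctx, fx.start, frag, fx.start, axis)
    # both contact spheres tangent at the shared accessible point
    assert np.linalg.norm(out[ap] - fx.start[a]) \
        == pytest.approx(r_a + r_ap, abs=1e-9)
    # a'-p' antiparallel to a-P: the placed ligand contact point coincides
    # with the site accessible point (tangent spheres, opposite normals)
    u = axis.site_point - fx.start[a]
    u /= np.linalg.norm(u)
    v0 = axis.ligand_point - fx.start[ap]
    from molsample.operators import align_rotation
    R = align_rotation(v0 / np.linalg.norm(v0), -u)
    lig = sorted(frag.atom_set)
    expected = (fx.start[lig] - fx.start[ap]) @ R.T \
        + axis.site_point + (r_ap) * u
    assert np.allclose(out[lig], expected, atol=1e-9)
    p_placed = (axis.ligand_point - fx.start[ap]) @ R.T + out[ap]
    v = p_placed - out[ap]
    v /= np.linalg.norm(v)
    assert float(np.dot(u, v)) == pytest.approx(-1.0, abs=1e-6)
    assert np.allclose(p_placed, axis.site_point, atol=1e-6)
    # site atoms untouched
    comp = sorted(frag.complement)
    assert np.array_equal(out[comp], fx.start[comp])


def test_uniform_torsional_crossover_inheritance(butane_ctx, butane_fx):
    ctx = butane_ctx
    p1 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(11))
    p2 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(12))
    child = uniform_torsional_crossover(ctx, p1, p2,
                                        np.random.default_rng(13),
                                        do_lo=False)
    for axis in ctx.torsion_axes:
        t = ctx.get_torsion(child, axis)
        choices = (ctx.get_torsion(p1, axis), ctx.get_torsion(p2, axis))
        assert any(abs(math.remainder(t - c, 2 * math.pi)) < 1e-6
                   for c in choices)
    # identical parents: child torsions identical pre-LO
    same = uniform_torsional_crossover(ctx, p1, p1,
                                       np.random.default_rng(14),
                                       do_lo=False)
    for axis in ctx.torsion_axes:
        assert abs(math.remainder(ctx.get_torsion(same, axis)
                                  - ctx.get_torsion(p1, axis),
                                  2 * math.pi)) < 1e-6


class _ConstantUniform:
    """rng stub whose uniform() always favors parent1 in the crossover."""

    def __init__(self, inner):
        self._inner = inner

    def uniform(self, *a, **k):
        if not a and not k:
            return 0.25
        return self._inner.uniform(*a, **k)

    def __getattr__(self, name):
        return getattr(self._inner, name)


def test_all_from_parent1_draw(butane_ctx, butane_fx):
    ctx = butane_ctx
    p1 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(21))
    p2 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(22))
    child = uniform_torsional_crossover(
        ctx, p1, p2, _ConstantUniform(np.random.default_rng(23)),
        do_lo=False)
    for axis in ctx.torsion_axes:
        assert abs(math.remainder(ctx.get_torsion(child, axis)
                                  - ctx.get_torsion(p1, axis),
                                  2 * math.pi)) < 1e-6


def test_cross_falls_through_without_eligible_fragments(butane_fx):
    # isolated molecule: its only fragment is loose with nothing to dock
    # against, so the recombination branch fails and cross must fall
    # through to the uniform torsional crossover
    ctx = SamplingContext(butane_fx.mol, get_scheme("core"),
                          min_fragment_size=99)
    assert all(f.kind == "loose" and not f.complement
               for f in ctx.fragments)
    p1 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(31))
    p2 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(32))
    a = cross(ctx, p1, p2, np.random.default_rng(33))
    # replay the dispatch draws, then the torsional branch
    rng = np.random.default_rng(33)
    if rng.uniform() < ctx.budget.fragment_recomb_probability:
        rng.integers(len(ctx.fragments))  # fragment pick before failure
    b = uniform_torsional_crossover(ctx, p1, p2, rng)
    assert np.array_equal(a, b)


def test_cross_seeded_reproducible(butane_ctx, butane_fx):
    ctx = butane_ctx
    p1 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(41))
    p2 = random_init(ctx, butane_fx.mol.coords, np.random.default_rng(42))
    a = cross(ctx, p1, p2, np.random.default_rng(7))
    b = cross(ctx, p1, p2, np.random.default_rng(7))
    assert np.array_equal(a, b)


def test_mutate_restraint_removed_from_energy(butane_fx):
    budget = OperatorBudget(driven_mutation_probability=1.0)
    ctx = SamplingContext(butane_fx.mol, get_scheme("core"), budget=budget)
    child = mutate(ctx, butane_fx.mol.coords, np.random.default_rng(51))
    assert ctx.model.torsion_restraints == []
    report = ctx.model.energy(child)
    assert report.terms["restraint"] == 0.0


def test_mutate_isolated_loose_fragment_falls_back():
    mol = _methane()
    ctx = SamplingContext(mol, get_scheme("core"))
    assert any(f.kind == "loose" for f in ctx.fragments)
    out = mutate(ctx, mol.coords, np.random.default_rng(52))
    assert out.shape == mol.coords.shape
    assert np.all(np.isfinite(out))


def test_random_init_no_moves_reduces_to_local_opt():
    mol = _methane()
    ctx = SamplingContext(mol, get_scheme("core"))
    assert ctx.torsion_axes == []
    a = random_init(ctx, mol.coords, np.random.default_rng(61))
    b = local_opt(ctx, mol.coords, np.random.default_rng(61))
    assert np.array_equal(a, b)


def test_random_init_deterministic_and_respects_fixed(cavity_ctx,
                                                      cavity_hydro_fx):
    fx = cavity_hydro_fx
    a = random_init(cavity_ctx, fx.start, np.random.default_rng(71))
    b = random_init(cavity_ctx, fx.start, np.random.default_rng(71))
    assert np.array_equal(a, b)
    fixed = np.flatnonzero(fx.mol.fixed_mask)
    assert np.array_equal(a[fixed], fx.start[fixed])
    assert not np.array_equal(a[list(fx.ligand_atoms)],
                              fx.start[list(fx.ligand_atoms)])


def test_operators_conserve_chirality(chiral_fx):
    ctx = SamplingContext(chiral_fx.mol, get_scheme("core"))
    rng = np.random.default_rng(81)
    coords = chiral_fx.mol.coords
    for k in range(30):
        if k % 3 == 0:
            coords = random_init(ctx, coords, rng)
        elif k % 3 == 1:
            coords = mutate(ctx, coords, rng)
        else:
            coords = cross(ctx, coords,
                           random_init(ctx, chiral_fx.mol.coords, rng), rng)
        assert ctx.model.energy(coords).terms["chirality"] \
            == pytest.approx(0.0, abs=1e-6)
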