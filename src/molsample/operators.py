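"""Genetic and local-search operators on conformations.

All operators act on full Cartesian coordinate arrays and are deterministic
given a :class:`numpy.random.Generator`.  Fixed atoms are never moved.  The
central moves are:

* *fragment recombination* -- the geometry of the larger moiety comes from
  one parent and the fragment's geometry from the other; for covalently
  bound fragments the cut bond is restored to its equilibrium geometry, for
  loose fragments (ligands) a random favorable contact axis plays the role
  of the bond.  The residual roll about the axis is resolved clash-driven
  (DockC) or energy-driven (DockE).
* *uniform torsional crossover* -- per-rotatable-bond inheritance of torsion
  values from a randomly chosen parent.
* *mutations* -- forced torsion changes (random jumps or restraint-driven)
  for bound fragments, self-recombination (repositioning) for loose ones.
* *Lamarckian local optimization (LO)* -- a short conjugate-gradient descent
  appended to every operator.
* *exhaustive minimization* -- alternating descent cycles on the nominal
  and a bond-softened energy surface, used to refine final poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .chem import Fragment, Molecule, _moieties, build_fragments, \
    detect_rotatable_bonds
from .forcefield import EnergyModel, TorsionRestraint, dihedral_angle, \
    _wrap_angle
from .params import FFParameters, ParameterScheme

PROBE_RADIUS = 1.1  # solvent probe used for contact spheres, Angstrom


class OperatorFailure(RuntimeError):
    """Raised when an operator cannot produce a viable geometry."""


@dataclass
class OperatorBudget:
    pair_pick_trials: int = 50
    dockc_max_attempts: int = 50
    docke_patience: int = 20
    lo_steps: tuple[int, int] = (20, 50)
    docke_probability: float = 0.30
    fragment_recomb_probability: float = 0.80
    accessible_trials: int = 50
    clash_factor: float = 0.75
    driven_mutation_k: float = 10.0  # kcal/mol/rad^2
    driven_mutation_probability: float = 0.5


@dataclass
class ContactAxis:
    """A favorable site-ligand contact acting as a temporary bond axis."""

    site_atom: int
    ligand_atom: int
    site_point: np.ndarray
    ligand_point: np.ndarray
    role: str  # "hydrophobic" | "hbond"


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    u = axis / max(np.linalg.norm(axis), 1e-12)
    c, s = math.cos(angle), math.sin(angle)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def align_rotation(u_from: np.ndarray, u_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u_from onto u_to."""
    a = u_from / max(np.linalg.norm(u_from), 1e-12)
    b = u_to / max(np.linalg.norm(u_to), 1e-12)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_matrix(perp, math.pi)
    return rotation_matrix(v, math.atan2(np.linalg.norm(v), c))


def rotate_about_line(coords: np.ndarray, idx: Sequence[int],
                      point: np.ndarray, axis: np.ndarray,
                      angle: float) -> None:
    """In-place rotation of ``idx`` atoms about the line (point, axis)."""
    R = rotation_matrix(axis, angle)
    coords[idx] = (coords[idx] - point) @ R.T + point


# ---------------------------------------------------------------------------
# sampling context: molecule + compiled energy + fragment machinery
# ---------------------------------------------------------------------------

@dataclass
class TorsionAxis:
    bond: tuple[int, int]       # (static end j, moving end k)
    quad: tuple[int, int, int, int]
    moving: np.ndarray          # atom indices rotated with the bond


class SamplingContext:
    """Everything the operators need for one molecular system."""

    def __init__(self, mol: Molecule, scheme: ParameterScheme,
                 params: Optional[FFParameters] = None,
                 hot_spots: Optional[Sequence[int]] = None,
                 budget: Optional[OperatorBudget] = None,
                 min_fragment_size: int = 5,
                 exclude_amide: bool = True):
        self.mol = mol
        self.model = EnergyModel(mol, scheme, params)
        self.budget = budget or OperatorBudget()
        self.hot_spots = list(hot_spots) if hot_spots is not None else None
        self.rotatable = detect_rotatable_bonds(mol,
                                                exclude_amide=exclude_amide)
        self.fragments = build_fragments(mol, min_size=min_fragment_size,
                                         rotatable=self.rotatable,
                                         exclude_amide=exclude_amide)
        self.torsion_axes = self._build_torsion_axes()
        self._vdw = np.array([a.vdw_radius for a in mol.atoms])

    # -- torsion machinery ---------------------------------------------------

    def _build_torsion_axes(self) -> list[TorsionAxis]:
        mol = self.mol
        fixed = mol.fixed_mask
        axes = []
        for b in self.rotatable:
            sides = _moieties(mol, b)
            if sides is None:
                continue
            eligible = [s for s in sides if not any(fixed[a] for a in s)]
            if not eligible:
                continue
            moving = min(eligible, key=lambda s: (len(s), min(s)))
            k = b.i if b.i in moving else b.j
            j = b.j if k == b.i else b.i
            nbrs_j = [x for x in sorted(mol.graph.neighbors(j)) if x != k]
            nbrs_k = [x for x in sorted(mol.graph.neighbors(k)) if x != j]
            if not nbrs_j or not nbrs_k:
                continue
            axes.append(TorsionAxis(bond=(j, k),
                                    quad=(nbrs_j[0], j, k, nbrs_k[0]),
                                    moving=np.array(sorted(moving),
                                                    dtype=int)))
        return axes

    def get_torsion(self, coords: np.ndarray, axis: TorsionAxis) -> float:
        return dihedral_angle(coords, *axis.quad)

    def set_torsion(self, coords: np.ndarray, axis: TorsionAxis,
                    value: float) -> None:
        """Rotate the moving side so the axis dihedral equals ``value``."""
        cur = self.get_torsion(coords, axis)
        delta = _wrap_angle(value - cur)
        j, k = axis.bond
        u = coords[k] - coords[j]
        rotate_about_line(coords, axis.moving, coords[j], u, delta)
        new = self.get_torsion(coords, axis)
        if abs(_wrap_angle(new - value)) > 1e-6:
            rotate_about_line(coords, axis.moving, coords[j], u, -2.0 * delta)

    # -- clash machinery -----------------------------------------------------

    def clash_score(self, coords: np.ndarray, moving: Sequence[int]) -> float:
        """Sum of overlaps below clash_factor * sum of vdW radii (0 = clean)."""
        moving = np.asarray(moving, dtype=int)
        rest = np.setdiff1d(np.arange(self.mol.n_atoms), moving)
        if len(rest) == 0 or len(moving) == 0:
            return 0.0
        T = self.mol.topo_dist[np.ix_(moving, rest)]
        d = np.linalg.norm(coords[moving][:, None, :]
                           - coords[rest][None, :, :], axis=2)
        limit = self.budget.clash_factor * (self._vdw[moving][:, None]
                                            + self._vdw[rest][None, :])
        overlap = np.where(T >= 3, np.maximum(limit - d, 0.0), 0.0)
        return float(np.sum(overlap))


# ---------------------------------------------------------------------------
# local optimization
# ---------------------------------------------------------------------------

MAX_ATOM_STEP = 0.5  # Angstrom per atom per CG iteration


def local_opt(ctx: SamplingContext, coords: np.ndarray,
              rng: Optional[np.random.Generator] = None,
              steps: Optional[int] = None) -> np.ndarray:
    """Lamarckian local optimization: short conjugate-gradient descent.

    The step count is drawn uniformly from [20, 50] unless given.  The
    output energy never exceeds the input energy (best-so-far retained);
    fixed atoms are bitwise unchanged.
    """
    model = ctx.model
    if steps is None:
        lo, hi = ctx.budget.lo_steps
        steps = int(rng.integers(lo, hi + 1)) if rng is not None else hi
    x = coords.copy()
    f, g = model.energy_and_gradient(x)
    if not np.isfinite(f):
        raise OperatorFailure("non-finite energy at local_opt entry")
    best_x, best_f = x.copy(), f
    d = -g
    gg = float(np.dot(g.ravel(), g.ravel()))
    alpha_prev = None
    for _ in range(steps):
        if gg < 1e-16:
            break
        max_disp = float(np.max(np.linalg.norm(d, axis=1)))
        if max_disp < 1e-14:
            break
        slope = float(np.dot(g.ravel(), d.ravel()))
        if slope >= 0:
            d = -g
            slope = -gg
            max_disp = float(np.max(np.linalg.norm(d, axis=1)))
        alpha = min(MAX_ATOM_STEP / max_disp, 1.0 / (1.0 + math.sqrt(gg)))
        if alpha_prev is not None:
            # warm-start from the last accepted step length
            alpha = min(alpha, 2.0 * alpha_prev)
        accepted = False
        for _bt in range(24):
            xn = x + alpha * d
            fn = model.energy(xn).total
            if np.isfinite(fn) and fn <= f + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        alpha_prev = alpha
        x = xn
        f, gn = model.energy_and_gradient(xn)
        if f < best_f:
            best_f, best_x = f, x.copy()
        gn_flat = gn.ravel()
        g_flat = g.ravel()
        beta = max(0.0, float(np.dot(gn_flat, gn_flat - g_flat)) / gg)
        d = -gn + beta * d
        g = gn
        gg = float(np.dot(gn_flat, gn_flat))
    return best_x


def exhaustive_minimize(ctx: SamplingContext, coords: np.ndarray,
                        rng: np.random.Generator,
                        tol: float = 1e-4,
                        max_cycles: int = 20,
                        maxiter: int = 200) -> np.ndarray:
    """Refinement by alternating nominal / bond-softened minimization.

    Each cycle runs a quasi-Newton descent on the nominal surface, then on a
    surface whose harmonic bond weight is drawn from (0, 0.2) -- softened
    bonds temporarily smooth the landscape so gradient methods escape
    shallow local minima -- and terminates when the nominal energy improves
    by less than ``tol`` kcal/mol between cycles.  Chirality penalties stay
    active throughout, so the softened passes cannot invert stereocenters.
    """
    model = ctx.model
    free = ctx.mol.free_atoms
    template = coords.copy()

    def objective(xf):
        x = template.copy()
        x[free] = xf.reshape(-1, 3)
        e, g = model.energy_and_gradient(x)
        return e, g[free].ravel()

    def descend(x0):
        res = scipy_minimize(objective, x0[free].ravel(), jac=True,
                             method="L-BFGS-B",
                             options={"maxiter": maxiter})
        x = template.copy()
        x[free] = res.x.reshape(-1, 3)
        return x

    x = coords.copy()
    if len(free) == 0:
        return x
    x = descend(x)
    e_prev = model.energy(x).total
    for _ in range(max_cycles):
        w = float(rng.uniform(0.0, 0.2))
        model.bond_weight = max(w, 1e-6)
        x_soft = descend(x)
        model.bond_weight = 1.0
        x_new = descend(x_soft)
        e_new = model.energy(x_new).total
        if e_new < e_prev - 1e-12:
            x = x_new
        if e_prev - e_new < tol:
            break
        e_prev = min(e_prev, e_new)
    model.bond_weight = 1.0
    return x


# ---------------------------------------------------------------------------
# contact-axis machinery for loose fragments
# ---------------------------------------------------------------------------

def accessible_point(atom: int, mol: Molecule, coords: np.ndarray,
                     rng: np.random.Generator,
                     among: Optional[Sequence[int]] = None,
                     probe: float = PROBE_RADIUS,
                     trials: int = 50) -> Optional[np.ndarray]:
    """Random solvent-accessible point on the atom's contact sphere.

    The sphere radius is vdW + probe; a candidate point is accessible if no
    other atom's center lies within that atom's own vdW + probe radius of
    the point.  Returns None after ``trials`` failures (buried atom).
    """
    if among is None:
        among = range(mol.n_atoms)
    others = np.array([i for i in among if i != atom], dtype=int)
    radius = mol.atoms[atom].vdw_radius + probe
    center = coords[atom]
    if len(others) == 0:
        v = rng.normal(size=3)
        return center + radius * v / np.linalg.norm(v)
    o_coords = coords[others]
    o_limit = np.array([mol.atoms[i].vdw_radius for i in others]) + probe
    for _ in range(trials):
        v = rng.normal(size=3)
        point = center + radius * v / max(np.linalg.norm(v), 1e-12)
        d = np.linalg.norm(o_coords - point, axis=1)
        if np.all(d >= o_limit):
            return point
    return None


def _contact_candidates(mol: Molecule, atoms: Sequence[int],
                        ligand_side: bool) -> list[int]:
    """Eligible contact partners: carbons, acceptors and donors."""
    out = []
    for i in atoms:
        a = mol.atoms[i]
        if a.role in ("donor_H", "acceptor", "hydrophobe"):
            out.append(i)
    return out


def _roles_match(mol: Molecule, a: int, b: int) -> Optional[str]:
    ra, rb = mol.atoms[a].role, mol.atoms[b].role
    if ra == rb == "hydrophobe":
        return "hydrophobic"
    if {ra, rb} == {"donor_H", "acceptor"}:
        return "hbond"
    return None


def draw_contact_axis(ctx: SamplingContext, coords: np.ndarray,
                      frag: Fragment, ligand_coords: np.ndarray,
                      rng: np.random.Generator) -> Optional[ContactAxis]:
    """Pick a matching (site atom, ligand atom) pair with accessible points.

    Site anchors come from the hot_spots list when the complement contains
    fixed atoms and a list was provided; otherwise every eligible complement
    atom is a candidate.  Up to ``pair_pick_trials`` pairs are tried.
    """
    mol = ctx.mol
    comp = sorted(frag.complement)
    fixed = mol.fixed_mask
    if ctx.hot_spots is not None and any(fixed[a] for a in comp):
        anchors = [a for a in ctx.hot_spots if a in frag.complement]
    else:
        anchors = _contact_candidates(mol, comp, ligand_side=False)
    lig_atoms = sorted(frag.atom_set)
    lig_contacts = _contact_candidates(mol, lig_atoms, ligand_side=True)
    if not anchors or not lig_contacts:
        return None
    for _ in range(ctx.budget.pair_pick_trials):
        a = int(anchors[rng.integers(len(anchors))])
        ap = int(lig_contacts[rng.integers(len(lig_contacts))])
        role = _roles_match(mol, a, ap)
        if role is None:
            continue
        P = accessible_point(a, mol, coords, rng, among=comp,
                             trials=ctx.budget.accessible_trials)
        if P is None:
            continue
        # the ligand-side point is sought within the fragment's own geometry
        pp = accessible_point(ap, mol, ligand_coords, rng, among=lig_atoms,
                              trials=ctx.budget.accessible_trials)
        if pp is None:
            continue
        return ContactAxis(site_atom=a, ligand_atom=ap, site_point=P,
                           ligand_point=pp, role=role)
    return None


def place_on_axis(ctx: SamplingContext, coords: np.ndarray,
                  frag: Fragment, source_coords: np.ndarray,
                  axis: ContactAxis) -> np.ndarray:
    """Rigidly place a loose fragment on a contact axis.

    The fragment geometry is taken from ``source_coords``; the contact atom
    a' ends up on the ray from the site atom a through its accessible point
    P, at tangent-contact distance (both contact spheres touch), with the
    vectors a'-p' and a-P antiparallel.
    """
    mol = ctx.mol
    lig = sorted(frag.atom_set)
    a, ap = axis.site_atom, axis.ligand_atom
    u = axis.site_point - coords[a]
    u = u / max(np.linalg.norm(u), 1e-12)
    v = axis.ligand_point - source_coords[ap]
    v = v / max(np.linalg.norm(v), 1e-12)
    R = align_rotation(v, -u)
    r_ap = mol.atoms[ap].vdw_radius + PROBE_RADIUS
    target_ap = axis.site_point + r_ap * u
    out = coords.copy()
    out[lig] = (source_coords[lig] - source_coords[ap]) @ R.T + target_ap
    return out


# ---------------------------------------------------------------------------
# DockC / DockE: resolving the roll about a new bond or contact axis
# ---------------------------------------------------------------------------

def dock_c(ctx: SamplingContext, coords: np.ndarray, moving: Sequence[int],
           point: np.ndarray, axis_dir: np.ndarray,
           rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Random rotations about the axis until clash-free (or best of 50)."""
    best = coords.copy()
    best_score = ctx.clash_score(coords, moving)
    if best_score == 0.0:
        return best, True
    for _ in range(ctx.budget.dockc_max_attempts):
        trial = coords.copy()
        angle = float(rng.uniform(0.0, 2.0 * math.pi))
        rotate_about_line(trial, moving, point, axis_dir, angle)
        score = ctx.clash_score(trial, moving)
        if score < best_score:
            best, best_score = trial, score
        if score == 0.0:
            return best, True
    return best, False


def dock_e(ctx: SamplingContext, coords: np.ndarray, moving: Sequence[int],
           point: np.ndarray, axis_dir: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    """Random rotations keeping the best energy; stop after 20 failures."""
    best = coords.copy()
    best_e = ctx.model.energy(best).total
    fails = 0
    while fails < ctx.budget.docke_patience:
        trial = coords.copy()
        angle = float(rng.uniform(0.0, 2.0 * math.pi))
        rotate_about_line(trial, moving, point, axis_dir, angle)
        e = ctx.model.energy(trial).total
        if e < best_e - 1e-12:
            best, best_e = trial, e
            fails = 0
        else:
            fails += 1
    return best


# ---------------------------------------------------------------------------
# recombination / crossover / mutation / initialization
# ---------------------------------------------------------------------------

def _restore_cut_bond(ctx: SamplingContext, child: np.ndarray,
                      parent1: np.ndarray, parent2: np.ndarray,
                      frag: Fragment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bound-fragment placement: re-import f from parent2 onto F of parent1."""
    mol = ctx.mol
    fa, fb = frag.pivot_bond  # fa in fragment, fb in complement
    lig = sorted(frag.atom_set)
    ti = mol.atoms[fa].ff_type
    tj = mol.atoms[fb].ff_type
    p = ctx.model.params.bond_param(ti, tj)
    r0 = p[1] if p else float(np.linalg.norm(parent1[fa] - parent1[fb]))
    u1 = parent1[fa] - parent1[fb]
    u1 = u1 / max(np.linalg.norm(u1), 1e-12)
    u2 = parent2[fa] - parent2[fb]
    u2 = u2 / max(np.linalg.norm(u2), 1e-12)
    R = align_rotation(u2, u1)
    anchor = child[fb] + r0 * u1
    child[lig] = (parent2[lig] - parent2[fa]) @ R.T + anchor
    return child, child[fb].copy(), u1


def fragment_recombination(ctx: SamplingContext, parent1: np.ndarray,
                           parent2: np.ndarray, rng: np.random.Generator,
                           frag: Optional[Fragment] = None,
                           do_lo: bool = True) -> np.ndarray:
    """Fragment-recombination crossover.

    F keeps the geometry of parent1; the fragment geometry is imported from
    parent2 and re-attached (bond restoration for bound fragments, contact
    axis placement for loose ones), the roll about the junction axis is
    resolved by DockC (or DockE in 30% of cases) and LO finishes the child.
    """
    if frag is None:
        if not ctx.fragments:
            raise OperatorFailure("molecule has no fragments")
        frag = ctx.fragments[rng.integers(len(ctx.fragments))]
    child = parent1.copy()
    if frag.kind == "bound":
        child, point, axis_dir = _restore_cut_bond(ctx, child, parent1,
                                                   parent2, frag)
        moving = sorted(frag.atom_set)
    else:
        axis = draw_contact_axis(ctx, child, frag, parent2, rng)
        if axis is None:
            raise OperatorFailure("no viable contact pair for loose fragment")
        child = place_on_axis(ctx, child, frag, parent2, axis)
        moving = sorted(frag.atom_set)
        point = child[axis.ligand_atom].copy()
        axis_dir = axis.site_point - child[axis.site_atom]
    if rng.uniform() < ctx.budget.docke_probability:
        child = dock_e(ctx, child, moving, point, axis_dir, rng)
    else:
        child, _ = dock_c(ctx, child, moving, point, axis_dir, rng)
    if do_lo:
        child = local_opt(ctx, child, rng)
    return child


def uniform_torsional_crossover(ctx: SamplingContext, parent1: np.ndarray,
                                parent2: np.ndarray,
                                rng: np.random.Generator,
                                do_lo: bool = True) -> np.ndarray:
    """Per-bond uniform inheritance of torsion values, then LO."""
    child = parent1.copy()
    for axis in ctx.torsion_axes:
        donor = parent1 if rng.uniform() < 0.5 else parent2
        ctx.set_torsion(child, axis, dihedral_angle(donor, *axis.quad))
    if do_lo:
        child = local_opt(ctx, child, rng)
    return child


def cross(ctx: SamplingContext, parent1: np.ndarray, parent2: np.ndarray,
          rng: np.random.Generator) -> np.ndarray:
    """Generic crossover: fragment recombination in 80% of calls.

    Falls through to the uniform torsional crossover when no fragment is
    eligible or the recombination fails to find a contact pair.
    """
    if ctx.fragments and rng.uniform() < ctx.budget.fragment_recomb_probability:
        try:
            return fragment_recombination(ctx, parent1, parent2, rng)
        except OperatorFailure:
            pass
    return uniform_torsional_crossover(ctx, parent1, parent2, rng)


def mutate(ctx: SamplingContext, parent: np.ndarray,
           rng: np.random.Generator) -> np.ndarray:
    """Forced change of one fragment's junction degree of freedom.

    Bound fragments: the pivot torsion is either reset to a random value or
    driven toward a random target by a temporary harmonic restraint that is
    active only during the LO and removed afterwards (the reported energy
    never contains it).  Loose fragments: self-recombination, i.e. the
    fragment is repositioned along a fresh contact axis.
    """
    if not ctx.fragments:
        # no fragments at all: plain torsion jump on a random axis, if any
        child = parent.copy()
        if ctx.torsion_axes:
            axis = ctx.torsion_axes[rng.integers(len(ctx.torsion_axes))]
            ctx.set_torsion(child, axis,
                            float(rng.uniform(-math.pi, math.pi)))
        return local_opt(ctx, child, rng)
    frag = ctx.fragments[rng.integers(len(ctx.fragments))]
    if frag.kind == "loose":
        try:
            return fragment_recombination(ctx, parent, parent, rng,
                                          frag=frag)
        except OperatorFailure:
            # an isolated molecule has no complement to dock against:
            # fall back to a plain torsion jump
            child = parent.copy()
            if ctx.torsion_axes:
                axis = ctx.torsion_axes[rng.integers(len(ctx.torsion_axes))]
                ctx.set_torsion(child, axis,
                                float(rng.uniform(-math.pi, math.pi)))
            return local_opt(ctx, child, rng)
    # find the torsion axis of the pivot bond
    fa, fb = frag.pivot_bond
    axis = next((t for t in ctx.torsion_axes
                 if set(t.bond) == {fa, fb}), None)
    child = parent.copy()
    target = float(rng.uniform(-math.pi, math.pi))
    if axis is None:
        return local_opt(ctx, child, rng)
    if rng.uniform() < ctx.budget.driven_mutation_probability:
        restraint = TorsionRestraint(quad=axis.quad,
                                     k=ctx.budget.driven_mutation_k,
                                     target=target)
        ctx.model.torsion_restraints.append(restraint)
        try:
            child = local_opt(ctx, child, rng)
        finally:
            ctx.model.torsion_restraints.remove(restraint)
        return child
    ctx.set_torsion(child, axis, target)
    return local_opt(ctx, child, rng)


def random_init(ctx: SamplingContext, coords: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Random initialization: torsion scrambling + DockC + LO.

    Every sampled torsion is randomized, each bound fragment is rotated
    clash-free about its pivot, each loose fragment is re-placed along a
    fresh random contact axis, and LO finishes the geometry.  Clashes may
    persist (the energy simply reflects them); fixed atoms never move.
    """
    child = coords.copy()
    for axis in ctx.torsion_axes:
        ctx.set_torsion(child, axis, float(rng.uniform(-math.pi, math.pi)))
    for frag in ctx.fragments:
        moving = sorted(frag.atom_set)
        if frag.kind == "bound":
            fa, fb = frag.pivot_bond
            axis_dir = child[fa] - child[fb]
            child, _ = dock_c(ctx, child, moving, child[fb], axis_dir, rng)
        else:
            axis = draw_contact_axis(ctx, child, frag, child, rng)
            if axis is None:
                continue  # keep the current placement
            child = place_on_axis(ctx, child, frag, child, axis)
            axis_dir = axis.site_point - child[axis.site_atom]
            child, _ = dock_c(ctx, child, moving,
                              child[axis.ligand_atom], axis_dir, rng)
    return local_opt(ctx, child, rng)
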