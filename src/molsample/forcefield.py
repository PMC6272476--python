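"""Potential energy and analytic gradient.

The energy is an AMBER/GAFF-style molecular mechanics sum (harmonic bonds
and angles, Fourier torsions, pairwise vdW and Coulomb) augmented with:

* a pairwise continuum *desolvation* penalty  sigma * (Qi^2 + Qj^2) / d^4,
* a distance-dependent dielectric  eps_r = epsilon * d  in the Coulomb term,
* smooth *contact bonuses* rewarding hydrophobic contacts and hydrogen
  bonds (implemented as negative energy contributions of magnitude
  kappa * C(d); the switching function C goes from 1 below d_min to 0 above
  d_max),
* a pair-specific cutoff with a smooth termination function
  w = (1 - d^2/cut^2)^2  multiplying every nonbonded pair term, and
* chirality / out-of-plane penalty terms that preserve the input
  configuration of stereocenters and the planarity of trigonal centers.

All 1/d^n terms use d^2 + d2offset (0.01 A^2) to avoid singularities.
Energies in kcal/mol, distances in Angstrom, charges in electrons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import Molecule, _equivalence_partition
from .params import (FFParameters, ParameterScheme, load_bundled_parameters)

COULOMB_CONST = 332.0
D2_OFFSET = 0.01
MAXCUT = 15.0
CUT_SCAN_STEP = 0.1
MIN_PAIR_CONTRIB = 0.01
HYDROPHOBIC_RANGE = (4.5, 5.5)   # Angstrom
HBOND_RANGE_DELTA = (-0.5, 0.1)  # relative to sum of vdW radii
K_CHIR = 100.0
K_OOP = 200.0
P_OOP = 0.01

# sp2 / planar force-field types whose 3-coordinate centers get an
# out-of-plane restraint
PLANAR_TYPES = {"c", "c2", "ca", "cc", "cd", "cp", "cq", "n", "n2", "na",
                "nb", "nc", "nd", "ne", "nf",
                "C", "CA", "CB", "CC", "CN", "CR", "CV", "CW", "C*", "N",
                "NB", "NC", "NY"}

HCLASS_INDEX = {"polarized": 0, "aromatic": 1, "aliphatic": 2}


# ---------------------------------------------------------------------------
# pure pairwise formulas (no cutoff weighting, no d2 offset)
# ---------------------------------------------------------------------------

def desolvation_pair(qi: float, qj: float, d: float, scheme: ParameterScheme,
                     is_ion_pair: bool = False,
                     is_hb_pair: bool = False) -> float:
    """Pairwise desolvation  sigma*(Qi^2+Qj^2)/d^4  with the scheme scalings.

    Returns 0 when max(|Qi|,|Qj|) < minq_to_desolv.  Pairs involving a metal
    cation are scaled by ``desolv_scale_ion``, polar-H/acceptor pairs by
    ``desolv_scale_hb`` (acceptor-acceptor and polarH-polarH pairs are not
    scaled).
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    if max(abs(qi), abs(qj)) < scheme.minq_to_desolv:
        return 0.0
    scale = 1.0
    if is_ion_pair:
        scale *= scheme.desolv_scale_ion
    elif is_hb_pair:
        scale *= scheme.desolv_scale_hb
    return scheme.desolv_factor * (qi * qi + qj * qj) / d ** 4 * scale


def coulomb_pair(qi: float, qj: float, d: float,
                 scheme: ParameterScheme) -> float:
    """Coulomb term with linearly distance-dependent dielectric (~ 1/d^2)."""
    if d <= 0:
        raise ValueError("distance must be positive")
    return COULOMB_CONST * qi * qj / (scheme.epsilon * d * d)


def contact_switch(d2, dmin2, dmax2):
    """Switching function C in [0,1]: 1 below d_min, 0 above d_max.

    Once-differentiable in d^2 at both edges of the switching range.
    """
    d2 = np.asarray(d2, dtype=float)
    t = (d2 - dmin2) / (dmax2 - dmin2)
    c = np.where(t <= 0.0, 1.0,
                 np.where(t >= 1.0, 0.0, 0.5 + 0.5 * np.cos(np.pi * np.clip(t, 0, 1))))
    return c if c.shape else float(c)


def contact_pair(atom_i, atom_j, d: float, scheme: ParameterScheme) -> float:
    """Contact bonus for a hydrophobe-hydrophobe or donorH-acceptor pair.

    Returned as a *negative* (stabilizing) contribution of magnitude
    kappa * C; kappa is ``hbond_bonus`` for H-bond pairs and the mean of the
    two carbon class constants for hydrophobic pairs.
    """
    roles = {atom_i.role, atom_j.role}
    if roles == {"hydrophobe"}:
        kappa = 0.5 * (scheme.hydrophobic_constant(atom_i.hydro_class)
                       + scheme.hydrophobic_constant(atom_j.hydro_class))
        dmin, dmax = HYDROPHOBIC_RANGE
    elif roles == {"donor_H", "acceptor"}:
        kappa = scheme.hbond_bonus
        svdw = atom_i.vdw_radius + atom_j.vdw_radius
        dmin, dmax = svdw + HBOND_RANGE_DELTA[0], svdw + HBOND_RANGE_DELTA[1]
    else:
        raise ValueError(f"pair roles {roles} are not contact-eligible")
    return -kappa * contact_switch(d * d, dmin * dmin, dmax * dmax)


def vdw_pair(a: float, b: float, d: float, scheme: ParameterScheme,
             vicinal: bool = False) -> float:
    """repulsive_factor*A/d^12 - B/d^6, scaled by vicinal_weight for 1-4."""
    if d <= 0:
        raise ValueError("distance must be positive")
    e = scheme.repulsive_factor * a / d ** 12 - b / d ** 6
    return e * (scheme.vicinal_weight if vicinal else 1.0)


def termination_weight(d, cut):
    """Smooth cutoff multiplier w = (1 - d^2/cut^2)^2, 0 beyond the cutoff."""
    if np.any(np.asarray(cut) <= 0):
        raise ValueError("cutoff must be positive")
    d = np.asarray(d, dtype=float)
    x = d * d / (cut * cut)
    w = np.where(x < 1.0, (1.0 - x) ** 2, 0.0)
    return w if w.shape else float(w)


def pair_cutoff_scan(energy_of_d, maxcut: float = MAXCUT,
                     step: float = CUT_SCAN_STEP,
                     min_contrib: float = MIN_PAIR_CONTRIB) -> float:
    """Backward-scan the distance range for the pair-specific cutoff.

    Starting from ``maxcut`` and stepping inward, the cutoff is the first
    (largest) scanned distance at which the total pairwise magnitude reaches
    ``min_contrib``; if it never does, the cutoff collapses to the smallest
    scanned distance (the pair is negligible and may be skipped).
    """
    d = maxcut
    while d >= step - 1e-12:
        if abs(energy_of_d(d)) >= min_contrib:
            return d
        d -= step
    return step


# ---------------------------------------------------------------------------
# chirality / out-of-plane references
# ---------------------------------------------------------------------------

@dataclass
class ChiralityReference:
    """Reference configuration of a stereocenter or trigonal center.

    Substituents are ordered by internal atom numbering (L, l, h, H); the
    signed projection p of the center onto the normal of the (l, h, H) face
    is recorded at the input geometry.  Tetrahedral centers are penalized by
    k_chir*|p| when the sign of p flips; trigonal centers by
    k_oop*(|p| - p_oop) when |p| exceeds p_oop.
    """

    center: int
    subs: tuple[int, ...]        # sorted substituent indices
    kind: str                    # "tetrahedral" | "trigonal"
    p0: float = 0.0
    k_chir: float = K_CHIR
    k_oop: float = K_OOP
    p_oop: float = P_OOP
    degenerate: bool = False


def signed_projection(coords: np.ndarray, center: int,
                      subs: Sequence[int]) -> float:
    """p = (c-l) . unit((H-l) x (h-l)) over the last three substituents."""
    l, h, hh = subs[-3], subs[-2], subs[-1]
    a = coords[hh] - coords[l]
    b = coords[h] - coords[l]
    n = np.cross(a, b)
    norm = np.linalg.norm(n)
    norm = max(norm, 1e-12)
    m = coords[center] - coords[l]
    return float(np.dot(m, n) / norm)


def chirality_penalty(coords: np.ndarray, ref: ChiralityReference) -> float:
    p = signed_projection(coords, ref.center, ref.subs)
    if ref.kind == "tetrahedral":
        if p * ref.p0 > 0:
            return 0.0
        return ref.k_chir * abs(p)
    # trigonal
    if abs(p) < ref.p_oop:
        return 0.0
    return ref.k_oop * (abs(p) - ref.p_oop)


def build_chirality_references(mol: Molecule,
                               coords: Optional[np.ndarray] = None
                               ) -> list[ChiralityReference]:
    """Register tetrahedral stereocenters and planar trigonal centers.

    A carbon with four substituents in four distinct topological
    equivalence classes is a stereocenter; 3-coordinate atoms of planar
    force-field types get an out-of-plane reference.
    """
    if coords is None:
        coords = mol.coords
    part = _equivalence_partition(mol)
    refs = []
    for a in mol.atoms:
        nbrs = tuple(sorted(mol.graph.neighbors(a.index)))
        if len(nbrs) == 4 and a.element == "C":
            if len({int(part[n]) for n in nbrs}) == 4:
                p0 = signed_projection(coords, a.index, nbrs)
                ref = ChiralityReference(center=a.index, subs=nbrs,
                                         kind="tetrahedral", p0=p0)
                if abs(p0) < 1e-6:
                    warnings.warn(f"near-planar tetrahedral center {a.index}")
                refs.append(ref)
        elif len(nbrs) == 3 and a.ff_type in PLANAR_TYPES:
            refs.append(ChiralityReference(center=a.index, subs=nbrs,
                                           kind="trigonal", p0=0.0))
    return refs


# ---------------------------------------------------------------------------
# energy report
# ---------------------------------------------------------------------------

TERM_NAMES = ("bond", "angle", "torsion", "vdw", "coulomb", "desolv",
              "contact", "chirality", "oop", "restraint")


@dataclass
class EnergyReport:
    total: float
    terms: dict[str, float]
    n_pairs: int = 0
    n_pairs_skipped: int = 0

    def __float__(self) -> float:
        return self.total


@dataclass
class TorsionRestraint:
    """Temporary harmonic torsional restraint k*(phi-target)^2 (driven moves)."""
    quad: tuple[int, int, int, int]
    k: float
    target: float  # radians


def assign_vdw_radii(mol: Molecule, params: Optional[FFParameters] = None
                     ) -> Molecule:
    params = params or load_bundled_parameters()
    for a in mol.atoms:
        try:
            a.vdw_radius = params.vdw_param(a.ff_type)[0]
        except KeyError:
            pass  # keep default; EnergyModel will complain if pairs need it
    return mol


# ---------------------------------------------------------------------------
# the compiled energy model
# ---------------------------------------------------------------------------

class EnergyModel:
    """Compiled energy/gradient evaluator for one molecule + scheme.

    Pair lists, parameters and pair-specific cutoffs are compiled once at
    construction (cutoffs cached per pair parameter type).  Terms entirely
    internal to the rigid (all-fixed) region -- bonded and nonbonded alike
    -- are constant by construction and excluded from the model (the
    rigid-receptor convention).  ``bond_weight`` (default 1.0) scales the harmonic bond
    term, used by the exhaustive minimizer's softened surface; temporary
    torsion restraints support driven mutations.
    """

    def __init__(self, mol: Molecule, scheme: ParameterScheme,
                 params: Optional[FFParameters] = None):
        self.mol = mol
        self.scheme = scheme
        self.params = params or load_bundled_parameters()
        self.bond_weight = 1.0
        self.torsion_restraints: list[TorsionRestraint] = []
        self.missing: list[str] = []
        assign_vdw_radii(mol, self.params)
        self._compile_bonded()
        fx = mol.fixed_mask
        self.chirality_refs = [
            r for r in build_chirality_references(mol)
            if not (fx[r.center] and all(fx[s] for s in r.subs))
        ]
        self._compile_nonbonded()
        if self.missing:
            raise KeyError("missing force-field parameters: "
                           + "; ".join(sorted(set(self.missing))))

    # -- compilation --------------------------------------------------------

    def _compile_bonded(self) -> None:
        mol, par = self.mol, self.params
        # bonded terms internal to the rigid (all-fixed) region are constant
        # by construction and are excluded outright (rigid-receptor model)
        fx = mol.fixed_mask
        bi, bj, bk, br0 = [], [], [], []
        for b in mol.bonds:
            if fx[b.i] and fx[b.j]:
                continue
            ti, tj = mol.atoms[b.i].ff_type, mol.atoms[b.j].ff_type
            p = par.bond_param(ti, tj)
            if p is None:
                self.missing.append(f"bond {ti}-{tj}")
                continue
            bi.append(b.i); bj.append(b.j); bk.append(p[0]); br0.append(p[1])
        self.b_i = np.array(bi, dtype=int)
        self.b_j = np.array(bj, dtype=int)
        self.b_k = np.array(bk)
        self.b_r0 = np.array(br0)

        ai, aj, ak, kk, tt = [], [], [], [], []
        deg = dict(mol.graph.degree())
        for j in range(mol.n_atoms):
            nbrs = sorted(mol.graph.neighbors(j))
            for x in range(len(nbrs)):
                for y in range(x + 1, len(nbrs)):
                    i, k = nbrs[x], nbrs[y]
                    if fx[i] and fx[j] and fx[k]:
                        continue
                    ti, tj, tk = (mol.atoms[i].ff_type, mol.atoms[j].ff_type,
                                  mol.atoms[k].ff_type)
                    kth, th0 = par.angle_param(ti, tj, tk,
                                               coordination=deg[j])
                    ai.append(i); aj.append(j); ak.append(k)
                    kk.append(kth); tt.append(math.radians(th0))
        self.a_i = np.array(ai, dtype=int)
        self.a_j = np.array(aj, dtype=int)
        self.a_k = np.array(ak, dtype=int)
        self.a_kth = np.array(kk)
        self.a_th0 = np.array(tt)

        rows = []  # (i, j, k, l, v_half, phase, n)
        for b in mol.bonds:
            j, k = b.i, b.j
            for i in mol.graph.neighbors(j):
                if i == k:
                    continue
                for l in mol.graph.neighbors(k):
                    if l == j or l == i:
                        continue
                    if fx[i] and fx[j] and fx[k] and fx[l]:
                        continue
                    ti, tj, tk, tl = (mol.atoms[i].ff_type,
                                      mol.atoms[j].ff_type,
                                      mol.atoms[k].ff_type,
                                      mol.atoms[l].ff_type)
                    for term in par.torsion_param(ti, tj, tk, tl):
                        if term.v_half != 0.0:
                            rows.append((i, j, k, l, term.v_half,
                                         term.phase, term.periodicity))
        if rows:
            arr = np.array(rows, dtype=float)
            self.t_idx = arr[:, :4].astype(int)
            self.t_v = arr[:, 4]
            self.t_phase = arr[:, 5]
            self.t_n = arr[:, 6]
        else:
            self.t_idx = np.zeros((0, 4), dtype=int)
            self.t_v = np.zeros(0)
            self.t_phase = np.zeros(0)
            self.t_n = np.zeros(0)

    def _pair_rows(self) -> tuple[np.ndarray, np.ndarray]:
        mol, sch, par = self.mol, self.scheme, self.params
        n = mol.n_atoms
        T = mol.topo_dist
        iu, ju = np.triu_indices(n, k=1)
        sep = T[iu, ju]
        mask = sep >= 3
        # pairs internal to the rigid region are constant and excluded,
        # matching the rigid-receptor treatment of the bonded terms
        fixed = mol.fixed_mask
        mask &= ~(fixed[iu] & fixed[ju])
        return iu[mask], ju[mask]

    def _compile_nonbonded(self) -> None:
        mol, sch, par = self.mol, self.scheme, self.params
        iu, ju = self._pair_rows()
        n_pairs = len(iu)
        q = mol.charges
        fixed = mol.fixed_mask
        rstar = np.zeros(mol.n_atoms)
        eps_w = np.zeros(mol.n_atoms)
        for a in mol.atoms:
            try:
                rstar[a.index], eps_w[a.index] = par.vdw_param(a.ff_type)
            except KeyError:
                self.missing.append(f"vdw {a.ff_type or a.element}")
        roles = np.array([{"none": 0, "donor_H": 1, "acceptor": 2,
                           "hydrophobe": 3}[a.role] for a in mol.atoms])
        hclass = np.array([HCLASS_INDEX.get(a.hydro_class, -1)
                           for a in mol.atoms])
        is_metal = np.array([mol.is_metal_cation(i)
                             for i in range(mol.n_atoms)])

        rij = rstar[iu] + rstar[ju]
        eij = np.sqrt(eps_w[iu] * eps_w[ju])
        A = eij * rij ** 12
        B = 2.0 * eij * rij ** 6
        qq = q[iu] * q[ju]
        sep = mol.topo_dist[iu, ju]
        vic = np.where(sep == 3, sch.vicinal_weight, 1.0)
        c14 = np.where(sep == 3, sch.coulomb14_scale, 1.0)

        # desolvation
        sigma = np.full(n_pairs, sch.desolv_factor)
        sigma[np.maximum(np.abs(q[iu]), np.abs(q[ju])) < sch.minq_to_desolv] = 0.0
        ion_pair = is_metal[iu] | is_metal[ju]
        hb_pair = ((roles[iu] == 1) & (roles[ju] == 2)) | \
                  ((roles[iu] == 2) & (roles[ju] == 1))
        sigma = np.where(ion_pair, sigma * sch.desolv_scale_ion,
                         np.where(hb_pair, sigma * sch.desolv_scale_hb, sigma))
        sigma_eff = sigma * (q[iu] ** 2 + q[ju] ** 2)

        # contact bonuses
        hydro_pair = (roles[iu] == 3) & (roles[ju] == 3)
        kc = np.array([sch.K_polarized, sch.K_arom, sch.K_aliph])
        kappa = np.zeros(n_pairs)
        dmin2 = np.zeros(n_pairs)
        dmax2 = np.zeros(n_pairs)
        has_contact = hydro_pair | hb_pair
        kappa[hydro_pair] = 0.5 * (kc[hclass[iu[hydro_pair]]]
                                   + kc[hclass[ju[hydro_pair]]])
        dmin2[hydro_pair] = HYDROPHOBIC_RANGE[0] ** 2
        dmax2[hydro_pair] = HYDROPHOBIC_RANGE[1] ** 2
        kappa[hb_pair] = sch.hbond_bonus
        svdw = rij[hb_pair]
        dmin2[hb_pair] = (svdw + HBOND_RANGE_DELTA[0]) ** 2
        dmax2[hb_pair] = (svdw + HBOND_RANGE_DELTA[1]) ** 2
        dmax2[~has_contact] = 0.0  # sentinel: no contact term
        # class-pair bookkeeping for the rescoring scan
        cls_pair = np.full(n_pairs, -1, dtype=int)
        ci, cj = hclass[iu], hclass[ju]
        lo = np.minimum(ci, cj); hi = np.maximum(ci, cj)
        cls_pair[hydro_pair] = (lo * 3 + hi)[hydro_pair]

        cut = self._pair_cutoffs(qq, c14, A, B, vic, sigma_eff,
                                 kappa, dmin2, dmax2)
        keep = cut > CUT_SCAN_STEP + 1e-9
        self.n_pairs_skipped = int(np.sum(~keep))

        data = dict(i=iu, j=ju, qq=qq, c14=c14, A=A, B=B, vic=vic,
                    sigma=sigma_eff, kappa=kappa, dmin2=dmin2, dmax2=dmax2,
                    cut2=cut ** 2, cls=cls_pair)
        both_fixed = fixed[iu] & fixed[ju]
        var = keep & ~both_fixed
        con = keep & both_fixed
        self.pairs = {k: v[var] for k, v in data.items()}
        const_pairs = {k: v[con] for k, v in data.items()}
        self.n_pairs = int(np.sum(keep))
        self._const_terms = self._nb_terms(const_pairs, mol.coords)[1] \
            if np.any(con) else {k: 0.0 for k in
                                 ("vdw", "coulomb", "desolv", "contact")}

    def _pair_cutoffs(self, qq, c14, A, B, vic, sigma_eff, kappa,
                      dmin2, dmax2) -> np.ndarray:
        """Pair-specific cutoffs, computed once per unique parameter tuple."""
        stack = np.column_stack([qq * c14, A, B, vic, sigma_eff,
                                 kappa, dmin2, dmax2])
        uniq, inv = np.unique(stack, axis=0, return_inverse=True)
        ds = np.arange(MAXCUT, CUT_SCAN_STEP - 1e-9, -CUT_SCAN_STEP)
        d2 = ds ** 2
        s = d2 + D2_OFFSET
        cuts = np.empty(len(uniq))
        sch = self.scheme
        for r, (qqc, a, b, v, sg, kp, dm, dx) in enumerate(uniq):
            e = COULOMB_CONST * qqc / (sch.epsilon * s)
            e = e + v * (sch.repulsive_factor * a / s ** 6 - b / s ** 3)
            e = e + sg / s ** 2
            if dx > 0:
                e = e - kp * contact_switch(d2, dm, dx)
            hit = np.abs(e) >= MIN_PAIR_CONTRIB
            idx = np.argmax(hit)
            cuts[r] = ds[idx] if hit.any() else CUT_SCAN_STEP
        return cuts[inv]

    # -- evaluation ---------------------------------------------------------

    def _nb_terms(self, P: dict, coords: np.ndarray,
                  want_grad: bool = False):
        ii, jj = P["i"], P["j"]
        dvec = coords[ii] - coords[jj]
        d2 = np.einsum("ij,ij->i", dvec, dvec)
        s = d2 + D2_OFFSET
        inv_s = 1.0 / s
        sch = self.scheme
        ecoul = COULOMB_CONST * P["qq"] * P["c14"] * inv_s / sch.epsilon
        inv_s3 = inv_s * inv_s * inv_s
        evdw = P["vic"] * (sch.repulsive_factor * P["A"] * inv_s3 * inv_s3
                           - P["B"] * inv_s3)
        edes = P["sigma"] * inv_s * inv_s
        rng = P["dmax2"] - P["dmin2"]
        has_c = P["dmax2"] > 0
        t = np.zeros_like(d2)
        np.divide(d2 - P["dmin2"], rng, out=t, where=has_c)
        in_sw = has_c & (t > 0.0) & (t < 1.0)
        C = np.where(has_c & (t <= 0.0), 1.0, 0.0)
        C[in_sw] = 0.5 + 0.5 * np.cos(np.pi * t[in_sw])
        econ = -P["kappa"] * C
        x = d2 / P["cut2"]
        inside = x < 1.0
        w = np.where(inside, (1.0 - x) ** 2, 0.0)
        esum = ecoul + evdw + edes + econ
        terms = {
            "coulomb": float(np.sum(w * ecoul)),
            "vdw": float(np.sum(w * evdw)),
            "desolv": float(np.sum(w * edes)),
            "contact": float(np.sum(w * econ)),
        }
        if not want_grad:
            return float(np.sum(w * esum)), terms
        # d/d(d2) of each factor
        dcoul = -ecoul * inv_s
        dvdw = P["vic"] * (-6.0 * sch.repulsive_factor * P["A"] * inv_s3
                           * inv_s3 * inv_s + 3.0 * P["B"] * inv_s3 * inv_s)
        ddes = -2.0 * edes * inv_s
        dC = np.zeros_like(d2)
        dC[in_sw] = -0.5 * np.pi * np.sin(np.pi * t[in_sw]) / rng[in_sw]
        dcon = -P["kappa"] * dC
        dw = np.where(inside, -2.0 * (1.0 - x) / P["cut2"], 0.0)
        dEdd2 = dw * esum + w * (dcoul + dvdw + ddes + dcon)
        coef = 2.0 * dEdd2
        g = np.zeros_like(coords)
        contrib = coef[:, None] * dvec
        nat = len(coords)
        for k in range(3):
            g[:, k] += np.bincount(ii, weights=contrib[:, k], minlength=nat)
            g[:, k] -= np.bincount(jj, weights=contrib[:, k], minlength=nat)
        return float(np.sum(w * esum)), terms, g

    def _bonded(self, coords: np.ndarray, want_grad: bool = False):
        g = np.zeros_like(coords) if want_grad else None
        terms = {}
        # bonds
        dvec = coords[self.b_i] - coords[self.b_j]
        r = np.linalg.norm(dvec, axis=1)
        dr = r - self.b_r0
        kb = self.bond_weight * self.b_k
        terms["bond"] = float(np.sum(kb * dr * dr))
        if want_grad and len(r):
            coef = (2.0 * kb * dr / np.maximum(r, 1e-12))[:, None] * dvec
            nat = len(coords)
            for k in range(3):
                g[:, k] += np.bincount(self.b_i, coef[:, k], minlength=nat)
                g[:, k] -= np.bincount(self.b_j, coef[:, k], minlength=nat)
        # angles
        u = coords[self.a_i] - coords[self.a_j]
        v = coords[self.a_k] - coords[self.a_j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / np.maximum(nu, 1e-12)[:, None]
        vh = v / np.maximum(nv, 1e-12)[:, None]
        cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dth = theta - self.a_th0
        terms["angle"] = float(np.sum(self.a_kth * dth * dth))
        if want_grad and len(theta):
            sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-8)
            dEdt = 2.0 * self.a_kth * dth
            gi = (cos_t[:, None] * uh - vh) / (nu * sin_t)[:, None]
            gk = (cos_t[:, None] * vh - uh) / (nv * sin_t)[:, None]
            ci = dEdt[:, None] * gi
            ck = dEdt[:, None] * gk
            nat = len(coords)
            for k in range(3):
                g[:, k] += np.bincount(self.a_i, ci[:, k], minlength=nat)
                g[:, k] += np.bincount(self.a_k, ck[:, k], minlength=nat)
                g[:, k] -= np.bincount(self.a_j, (ci + ck)[:, k],
                                       minlength=nat)
        # torsions
        e_t, g_t = self._torsion_energy(coords, self.t_idx, want_grad,
                                        v_half=self.t_v, phase=self.t_phase,
                                        period=self.t_n)
        terms["torsion"] = e_t
        if want_grad and g_t is not None:
            g += g_t
        # restraints
        e_r = 0.0
        for rs in self.torsion_restraints:
            quad = np.array([rs.quad])
            phi, dphi_dx = _dihedral(coords, quad, want_grad)
            dphi = _wrap_angle(phi[0] - rs.target)
            e_r += rs.k * dphi * dphi
            if want_grad:
                for m, idx in enumerate(rs.quad):
                    g[idx] += 2.0 * rs.k * dphi * dphi_dx[0, m]
        terms["restraint"] = e_r
        return terms, g

    def _torsion_energy(self, coords, quads, want_grad, v_half, phase,
                        period):
        if len(quads) == 0:
            return 0.0, (np.zeros_like(coords) if want_grad else None)
        phi, dphi = _dihedral(coords, quads, want_grad)
        arg = period * phi - phase
        e = float(np.sum(v_half * (1.0 + np.cos(arg))))
        if not want_grad:
            return e, None
        dEdphi = -v_half * period * np.sin(arg)
        g = np.zeros_like(coords)
        for m in range(4):
            contrib = dEdphi[:, None] * dphi[:, m]
            idx = quads[:, m]
            for k in range(3):
                g[:, k] += np.bincount(idx, contrib[:, k],
                                       minlength=len(coords))
        return e, g

    def _chirality_arrays(self):
        arrs = getattr(self, "_chir_cache", None)
        if arrs is None:
            refs = self.chirality_refs
            arrs = {
                "c": np.array([r.center for r in refs], dtype=int),
                "l": np.array([r.subs[-3] for r in refs], dtype=int),
                "h": np.array([r.subs[-2] for r in refs], dtype=int),
                "hh": np.array([r.subs[-1] for r in refs], dtype=int),
                "tet": np.array([r.kind == "tetrahedral" for r in refs]),
                "p0": np.array([r.p0 for r in refs]),
                "kchir": np.array([r.k_chir for r in refs]),
                "koop": np.array([r.k_oop for r in refs]),
                "poop": np.array([r.p_oop for r in refs]),
            }
            self._chir_cache = arrs
        return arrs

    def _chirality(self, coords: np.ndarray, want_grad: bool = False):
        g = np.zeros_like(coords) if want_grad else None
        refs = self.chirality_refs
        if not refs:
            return 0.0, 0.0, g
        A = self._chirality_arrays()
        pl = coords[A["l"]]
        a = coords[A["hh"]] - pl
        b = coords[A["h"]] - pl
        n = _cross(a, b)
        norm = np.sqrt(np.einsum("ij,ij->i", n, n))
        small = norm < 1e-12
        if small.any():
            for idx in np.nonzero(small)[0]:
                refs[idx].degenerate = True
            norm = np.maximum(norm, 1e-12)
        nh = n / norm[:, None]
        m = coords[A["c"]] - pl
        p = np.einsum("ij,ij->i", m, nh)
        tet = A["tet"]
        act_t = tet & (p * A["p0"] <= 0.0)
        act_o = ~tet & (np.abs(p) >= A["poop"])
        e_chir = float(np.sum(A["kchir"][act_t] * np.abs(p[act_t])))
        e_oop = float(np.sum(A["koop"][act_o]
                             * (np.abs(p[act_o]) - A["poop"][act_o])))
        if not want_grad:
            return e_chir, e_oop, None
        sgn = np.where(p >= 0.0, 1.0, -1.0)
        dpen = np.zeros(len(refs))
        dpen[act_t] = A["kchir"][act_t] * sgn[act_t]
        dpen[act_o] = A["koop"][act_o] * sgn[act_o]
        if np.any(dpen != 0.0):
            # p = (m.n)/|n| with n = a x b
            inv = (1.0 / norm)[:, None]
            ga = (_cross(b, m) - p[:, None] * _cross(b, nh)) * inv
            gb = (_cross(m, a) - p[:, None] * _cross(nh, a)) * inv
            w = dpen[:, None]
            ca = w * ga
            cb = w * gb
            cc = w * nh
            cl = -(ca + cb + cc)
            nat = len(coords)
            for k in range(3):
                g[:, k] += np.bincount(A["hh"], ca[:, k], minlength=nat)
                g[:, k] += np.bincount(A["h"], cb[:, k], minlength=nat)
                g[:, k] += np.bincount(A["c"], cc[:, k], minlength=nat)
                g[:, k] += np.bincount(A["l"], cl[:, k], minlength=nat)
        return e_chir, e_oop, g

    def energy(self, coords: np.ndarray) -> EnergyReport:
        terms, _ = self._bonded(coords, want_grad=False)
        e_nb, nb_terms = self._nb_terms(self.pairs, coords)
        for k, v in nb_terms.items():
            terms[k] = v + self._const_terms[k]
        e_chir, e_oop, _ = self._chirality(coords)
        terms["chirality"] = e_chir
        terms["oop"] = e_oop
        total = float(sum(terms.values()))
        return EnergyReport(total=total, terms=terms, n_pairs=self.n_pairs,
                            n_pairs_skipped=self.n_pairs_skipped)

    def energy_and_gradient(self, coords: np.ndarray
                            ) -> tuple[float, np.ndarray]:
        terms, g = self._bonded(coords, want_grad=True)
        e_nb, nb_terms, g_nb = self._nb_terms(self.pairs, coords,
                                              want_grad=True)
        g += g_nb
        e_chir, e_oop, g_c = self._chirality(coords, want_grad=True)
        g += g_c
        total = (sum(terms.values()) + e_nb + e_chir + e_oop
                 + sum(self._const_terms.values()))
        g[self.mol.fixed_mask] = 0.0
        return float(total), g

    # -- decomposition used by the hydrophobic-triplet rescoring scan -------

    def hydrophobic_decomposition(self, coords: np.ndarray
                                  ) -> tuple[float, np.ndarray]:
        """(energy with all K_c = 0, 3x3 matrix S of per-class-pair sums).

        The hydrophobic contact energy is linear in the class constants:
        E(K) = E0 - sum_{c1<=c2} S[c1,c2] * (K_c1 + K_c2)/2, which lets the
        1000-triplet scan rescore poses without re-evaluating every pair.
        """
        P = self.pairs
        ii, jj = P["i"], P["j"]
        dvec = coords[ii] - coords[jj]
        d2 = np.einsum("ij,ij->i", dvec, dvec)
        x = d2 / P["cut2"]
        w = np.where(x < 1.0, (1.0 - x) ** 2, 0.0)
        hydro = P["cls"] >= 0
        C = contact_switch(d2[hydro], P["dmin2"][hydro], P["dmax2"][hydro])
        wc = w[hydro] * C
        S = np.zeros((3, 3))
        cls = P["cls"][hydro]
        for cp in np.unique(cls):
            c1, c2 = divmod(int(cp), 3)
            S[c1, c2] += float(np.sum(wc[cls == cp]))
        rep = self.energy(coords)
        kcs = (self.scheme.K_polarized, self.scheme.K_arom,
               self.scheme.K_aliph)
        e_hydro = -sum(S[c1, c2] * 0.5 * (kcs[c1] + kcs[c2])
                       for c1 in range(3) for c2 in range(c1, 3))
        return rep.total - e_hydro, S


def triplet_energy(e_zero_k: float, S: np.ndarray,
                   triplet: Sequence[float]) -> float:
    """Total energy under a (K_polarized, K_arom, K_aliph) triplet."""
    return e_zero_k - sum(S[c1, c2] * 0.5 * (triplet[c1] + triplet[c2])
                          for c1 in range(3) for c2 in range(c1, 3))


def energy_total(mol: Molecule, coords: np.ndarray, scheme: ParameterScheme,
                 params: Optional[FFParameters] = None) -> EnergyReport:
    """One-shot total energy (builds a transient :class:`EnergyModel`)."""
    return EnergyModel(mol, scheme, params).energy(coords)


def energy_gradient(mol: Molecule, coords: np.ndarray,
                    scheme: ParameterScheme,
                    params: Optional[FFParameters] = None
                    ) -> tuple[float, np.ndarray]:
    return EnergyModel(mol, scheme, params).energy_and_gradient(coords)


# ---------------------------------------------------------------------------
# dihedral geometry
# ---------------------------------------------------------------------------

def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product (avoids np.cross overhead on small arrays)."""
    out = np.empty_like(a)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int
                   ) -> float:
    phi, _ = _dihedral(coords, np.array([[i, j, k, l]]), False)
    return float(phi[0])


def _dihedral(coords: np.ndarray, quads: np.ndarray, want_grad: bool):
    """Signed dihedral angles (and, optionally, d(phi)/d(coords))."""
    p0 = coords[quads[:, 0]]
    p1 = coords[quads[:, 1]]
    p2 = coords[quads[:, 2]]
    p3 = coords[quads[:, 3]]
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m1 = _cross(n1, b2 / np.maximum(nb2, 1e-12)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)
    if not want_grad:
        return phi, None
    sn1 = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-24)
    sn2 = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-24)
    dphi0 = (nb2 / sn1)[:, None] * n1
    dphi3 = -(nb2 / sn2)[:, None] * n2
    s12 = np.einsum("ij,ij->i", b1, b2) / np.maximum(nb2 ** 2, 1e-24)
    s32 = np.einsum("ij,ij->i", b3, b2) / np.maximum(nb2 ** 2, 1e-24)
    dphi1 = -(1.0 + s12)[:, None] * dphi0 + s32[:, None] * dphi3
    dphi2 = s12[:, None] * dphi0 - (1.0 + s32)[:, None] * dphi3
    return phi, np.stack([dphi0, dphi1, dphi2, dphi3], axis=1)
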