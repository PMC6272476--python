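"""Structure and configuration I/O.

SDF files are read and written through RDKit; force-field types, partial
charges and fixed-atom flags travel as SD tags so that a round trip loses
no typing information.  TRIPOS MOL2 is parsed directly (multi-record,
SYBYL atom types mapped to the internal GAFF-style types, partial charges
from column 9).  The legacy ``car`` format is not supported.

Auxiliary text formats: fixed-atom lists and hot-spot lists (1-based
indices, ``#`` comments), and YAML/key-value run configuration files.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Geometry import Point3D

from .chem import Atom, Bond, Molecule, assign_interaction_roles
from .evolution import EvolutionConfig
from .forcefield import assign_vdw_radii
from .params import ParameterScheme, get_scheme, load_bundled_parameters, \
    load_sybyl_map

_BOND_ORDER_TO_RDKIT = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                        3: Chem.BondType.TRIPLE}
_RDKIT_TO_BOND_ORDER = {v: k for k, v in _BOND_ORDER_TO_RDKIT.items()}

# two-letter elements that occur as force-field type prefixes
_TWO_LETTER = ("Cl", "Br", "Zn", "Mg", "Ca", "Na", "Fe", "Mn", "Cu", "Ni",
               "Co", "Li", "cl", "br")


def element_of_type(ff_type: str) -> str:
    """Element symbol from a GAFF-style or AMBER type name."""
    for two in _TWO_LETTER:
        if ff_type.startswith(two):
            return two.capitalize()
    if not ff_type:
        raise ValueError("empty force-field type")
    first = ff_type[0].upper()
    if first not in "CHNOSPFIK":
        raise ValueError(f"cannot infer element from type {ff_type!r}")
    return "K" if ff_type in ("K", "K+") else first


# ---------------------------------------------------------------------------
# SDF via RDKit
# ---------------------------------------------------------------------------

def molecule_to_rdkit(mol: Molecule, name: str = "",
                      extra_tags: Optional[dict] = None) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetNoImplicit(True)
        ra.SetFormalCharge(a.formal_charge)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _BOND_ORDER_TO_RDKIT.get(b.order,
                                                      Chem.BondType.SINGLE))
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m = rw.GetMol()
    m.AddConformer(conf)
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
    m.SetProp("_Name", name or "molecule")
    m.SetProp("FF_TYPES", " ".join(a.ff_type for a in mol.atoms))
    m.SetProp("PARTIAL_CHARGES",
              " ".join(f"{a.charge:.6f}" for a in mol.atoms))
    fixed = [str(a.index + 1) for a in mol.atoms if a.fixed]
    if fixed:
        m.SetProp("FIXED_ATOMS", " ".join(fixed))
    for key, value in (extra_tags or {}).items():
        m.SetProp(str(key), str(value))
    return m


def rdkit_to_molecule(rdmol: Chem.Mol) -> Molecule:
    conf = rdmol.GetConformer()
    types = rdmol.GetProp("FF_TYPES").split() \
        if rdmol.HasProp("FF_TYPES") else [""] * rdmol.GetNumAtoms()
    if rdmol.HasProp("PARTIAL_CHARGES"):
        charges = [float(x) for x in
                   rdmol.GetProp("PARTIAL_CHARGES").split()]
    else:
        warnings.warn("SDF record lacks PARTIAL_CHARGES; charges set to 0")
        charges = [0.0] * rdmol.GetNumAtoms()
    fixed = set()
    if rdmol.HasProp("FIXED_ATOMS"):
        fixed = {int(x) - 1 for x in rdmol.GetProp("FIXED_ATOMS").split()}
    atoms, coords = [], []
    for i, a in enumerate(rdmol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        coords.append([p.x, p.y, p.z])
        atoms.append(Atom(index=i, element=a.GetSymbol(),
                          ff_type=types[i], charge=charges[i],
                          fixed=i in fixed,
                          formal_charge=a.GetFormalCharge()))
    bonds = [Bond(i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(),
                  order=_RDKIT_TO_BOND_ORDER.get(b.GetBondType(), 1))
             for b in rdmol.GetBonds()]
    mol = Molecule(atoms, bonds, np.array(coords))
    _finalize(mol)
    return mol


def write_sdf(path: str, molecules: Sequence[Molecule],
              names: Optional[Sequence[str]] = None,
              extra_tags: Optional[Sequence[dict]] = None) -> None:
    writer = Chem.SDWriter(str(path))
    for k, mol in enumerate(molecules):
        name = names[k] if names else f"record_{k}"
        tags = extra_tags[k] if extra_tags else None
        writer.write(molecule_to_rdkit(mol, name=name, extra_tags=tags))
    writer.close()


def read_sdf(path: str) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out = []
    for rdmol in supplier:
        if rdmol is None:
            raise ValueError(f"unparsable record in {path}")
        out.append(rdkit_to_molecule(rdmol))
    if not out:
        raise ValueError(f"no records in {path}")
    return out


# ---------------------------------------------------------------------------
# TRIPOS MOL2
# ---------------------------------------------------------------------------

_MOL2_BOND_ORDER = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1, "du": 1,
                    "un": 1, "nc": 1}


def read_mol2(path: str) -> list[Molecule]:
    """Multi-record TRIPOS MOL2 reader with SYBYL type mapping."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    sybyl_map = load_sybyl_map()
    known_gaff = set(load_bundled_parameters().vdw)
    records: list[Molecule] = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "@<TRIPOS>MOLECULE":
            i += 1
            continue
        rec_start = i
        i += 1
        block: dict[str, list[tuple[int, str]]] = {}
        section = None
        while i < n and lines[i].strip() != "@<TRIPOS>MOLECULE":
            line = lines[i]
            if line.startswith("@<TRIPOS>"):
                section = line.strip()[len("@<TRIPOS>"):]
                block.setdefault(section, [])
            elif section is not None and line.strip():
                block[section].append((i + 1, line))
            i += 1
        records.append(_parse_mol2_record(block, rec_start + 1, sybyl_map,
                                          known_gaff))
    if not records:
        raise ValueError(f"no MOL2 records in {path}")
    return records


def _parse_mol2_record(block, lineno, sybyl_map, known_gaff) -> Molecule:
    atoms, coords = [], []
    raw_types = []
    for ln, line in block.get("ATOM", []):
        parts = line.split()
        try:
            idx = int(parts[0]) - 1
            name = parts[1]
            xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
            sybyl = parts[5]
            resid = int(parts[6]) if len(parts) > 6 else 1
            resname = parts[7] if len(parts) > 7 else "LIG"
            charge = float(parts[8]) if len(parts) > 8 else None
        except (IndexError, ValueError) as exc:
            raise ValueError(f"MOL2 atom parse error at line {ln}") from exc
        if charge is None:
            warnings.warn(f"missing charge at line {ln}; set to 0")
            charge = 0.0
        raw_types.append((ln, sybyl))
        coords.append(xyz)
        atoms.append(Atom(index=idx, element="", ff_type="", charge=charge,
                          name=name, resid=resid, resname=resname))
    bonds = []
    for ln, line in block.get("BOND", []):
        parts = line.split()
        try:
            bi, bj = int(parts[1]) - 1, int(parts[2]) - 1
            order = _MOL2_BOND_ORDER[parts[3].lower()]
        except (IndexError, ValueError, KeyError) as exc:
            raise ValueError(f"MOL2 bond parse error at line {ln}") from exc
        bonds.append(Bond(i=bi, j=bj, order=order))
    if not atoms:
        raise ValueError(f"MOL2 record at line {lineno} has no atoms")
    mol = Molecule(atoms, bonds, np.array(coords))
    # resolve force-field types (needs bonds for polar-H disambiguation)
    for a, (ln, sybyl) in zip(mol.atoms, raw_types):
        if sybyl in sybyl_map:
            ff = sybyl_map[sybyl]
        elif sybyl in known_gaff:
            ff = sybyl  # already an internal GAFF-style type
        else:
            raise ValueError(f"unmapped atom type {sybyl!r} at line {ln}")
        if ff == "*H":
            ff = _polar_h_type(mol, a.index)
        a.ff_type = ff
        a.element = element_of_type(ff) if "." not in sybyl else \
            sybyl.split(".")[0].capitalize()
        if a.element.lower() == a.element and len(a.element) == 1:
            a.element = a.element.upper()
    _finalize(mol)
    return mol


def _polar_h_type(mol: Molecule, h_index: int) -> str:
    neighbors = list(mol.graph.neighbors(h_index))
    if not neighbors:
        return "hc"
    heavy = mol.atoms[neighbors[0]]
    partner = heavy.ff_type or heavy.element
    first = partner[:1].lower()
    if first == "o":
        return "ho"
    if first == "n":
        return "hn"
    if first == "s":
        return "hs"
    if partner in ("ca", "C.ar") or partner.startswith("C.ar"):
        return "ha"
    return "hc"


_GAFF_TO_SYBYL = None


def _gaff_to_sybyl() -> dict[str, str]:
    global _GAFF_TO_SYBYL
    if _GAFF_TO_SYBYL is None:
        inv: dict[str, str] = {}
        for sybyl, gaff in load_sybyl_map().items():
            inv.setdefault(gaff, sybyl)
        _GAFF_TO_SYBYL = inv
    return _GAFF_TO_SYBYL


def write_mol2(path: str, molecules: Sequence[Molecule],
               names: Optional[Sequence[str]] = None) -> None:
    """MOL2 writer; internal types are written verbatim in the type column
    (the reader accepts them), preserving an exact type round trip."""
    out = []
    for k, mol in enumerate(molecules):
        name = names[k] if names else f"record_{k}"
        out.append("@<TRIPOS>MOLECULE")
        out.append(name)
        out.append(f"{mol.n_atoms} {len(mol.bonds)} 0 0 0")
        out.append("SMALL")
        out.append("USER_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for a in mol.atoms:
            x, y, z = mol.coords[a.index]
            out.append(f"{a.index + 1:>6} {a.name or a.element:<6} "
                       f"{x:>10.4f} {y:>10.4f} {z:>10.4f} "
                       f"{a.ff_type:<6} {a.resid:>3} {a.resname:<6} "
                       f"{a.charge:>9.4f}")
        out.append("@<TRIPOS>BOND")
        for k2, b in enumerate(mol.bonds):
            out.append(f"{k2 + 1:>6} {b.i + 1:>6} {b.j + 1:>6} {b.order}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_structure(path: str, fmt: Optional[str] = None) -> list[Molecule]:
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt == "sdf":
        return read_sdf(path)
    if fmt == "mol2":
        return read_mol2(path)
    if fmt == "car":
        raise NotImplementedError("the car format is not supported; "
                                  "convert to sdf or mol2")
    raise ValueError(f"unknown structure format {fmt!r}")


def _finalize(mol: Molecule) -> None:
    assign_interaction_roles(mol)
    try:
        assign_vdw_radii(mol)
    except KeyError:
        warnings.warn("some atoms lack vdW parameters; radii left default")


# ---------------------------------------------------------------------------
# index lists and configuration
# ---------------------------------------------------------------------------

def read_index_list(path: str) -> list[int]:
    """1-based index list (whitespace separated, # comments) -> 0-based."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            for tok in line.split():
                idx = int(tok)
                if idx < 1:
                    raise ValueError("indices are 1-based and positive")
                out.append(idx - 1)
    return out


def write_index_list(path: str, indices: Sequence[int],
                     comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(" ".join(str(i + 1) for i in indices) + "\n")


def load_run_config(path: str) -> tuple[EvolutionConfig, ParameterScheme]:
    """YAML (or key: value) run configuration.

    Recognized keys: every EvolutionConfig field, plus ``scheme`` (name of a
    parameter scheme) and optional ``K_polarized/K_arom/K_aliph`` overrides.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("run configuration must be a mapping")
    scheme = get_scheme(str(data.pop("scheme", "fit")))
    triplet = [data.pop(k, None) for k in
               ("K_polarized", "K_arom", "K_aliph")]
    if any(v is not None for v in triplet):
        current = (scheme.K_polarized, scheme.K_arom, scheme.K_aliph)
        scheme = scheme.with_triplet(*[float(v) if v is not None else c
                                       for v, c in zip(triplet, current)])
    fields = {f.name for f in dataclasses.fields(EvolutionConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return EvolutionConfig(**data), scheme
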