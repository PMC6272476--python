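"""Force-field parameter handling.

Bonded terms (harmonic bonds and angles, Fourier torsions) and vdW
well parameters are looked up by force-field type, read from AMBER
parm/frcmod-style text files.  A minimal bundled set covers the common
organic types plus halogens and metal cations; external files override it.

The three named parameter *schemes* (core / preliminary / fit) collect the
tunable weights of the augmented energy function: distance-dependent
dielectric slope, vdW repulsion scaling, vicinal (1-4) vdW weight,
desolvation strength and scaling, H-bond bonus and the per-class
hydrophobic contact constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

DEG = math.pi / 180.0


@dataclass
class TorsionTerm:
    v_half: float      # PK/IDIVF, kcal/mol
    phase: float       # radians
    periodicity: int


@dataclass
class FFParameters:
    """Bonded + vdW parameter tables keyed by force-field type."""

    bond: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angle: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    torsion: dict[tuple[str, str, str, str], list[TorsionTerm]] = field(default_factory=dict)
    vdw: dict[str, tuple[float, float]] = field(default_factory=dict)  # r* (A), eps
    mass: dict[str, float] = field(default_factory=dict)

    # -- lookups with wildcard / fallback handling --------------------------

    def bond_param(self, ti: str, tj: str) -> Optional[tuple[float, float]]:
        return self.bond.get((ti, tj)) or self.bond.get((tj, ti))

    def angle_param(self, ti: str, tj: str, tk: str,
                    coordination: int = 4) -> tuple[float, float]:
        p = self.angle.get((ti, tj, tk)) or self.angle.get((tk, tj, ti))
        if p is not None:
            return p
        # generic fallback by central-atom coordination
        theta0 = {2: 180.0, 3: 120.0}.get(coordination, 109.47)
        return (60.0, theta0)

    def torsion_param(self, ti: str, tj: str, tk: str, tl: str
                      ) -> list[TorsionTerm]:
        for key in ((ti, tj, tk, tl), (tl, tk, tj, ti),
                    ("X", tj, tk, "X"), ("X", tk, tj, "X")):
            if key in self.torsion:
                return self.torsion[key]
        return []

    def vdw_param(self, t: str) -> tuple[float, float]:
        if t in self.vdw:
            return self.vdw[t]
        raise KeyError(f"no vdW parameters for type {t!r}")

    def update(self, other: "FFParameters") -> None:
        self.bond.update(other.bond)
        self.angle.update(other.angle)
        self.torsion.update(other.torsion)
        self.vdw.update(other.vdw)
        self.mass.update(other.mass)


def read_frcmod(path_or_text: str, is_text: bool = False) -> FFParameters:
    """Read an AMBER parm/frcmod-style parameter file.

    Recognized sections: MASS, BOND, ANGLE, DIHE, NONBON.  Dihedral lines
    follow the AMBER convention ``types IDIVF PK PHASE PN`` (energy
    PK/IDIVF * (1 + cos(PN*phi - PHASE))); a negative PN would indicate
    additional terms on following lines (all terms are simply accumulated
    per type quadruple here).
    """
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    p = FFParameters()
    section = None
    headers = {"MASS", "BOND", "ANGLE", "DIHE", "DIHEDRAL", "IMPROPER",
               "NONBON", "NONB", "NONBONDED"}
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line.strip():
            continue
        token = line.strip().upper()
        if token in headers:
            section = "DIHE" if token == "DIHEDRAL" else token
            if section in ("NONB", "NONBONDED"):
                section = "NONBON"
            continue
        if section is None:
            continue  # title/comment lines before the first section
        try:
            if section == "MASS":
                t, m = _split_types(line, 1)
                p.mass[t[0]] = float(m[0])
            elif section == "BOND":
                t, vals = _split_types(line, 2)
                p.bond[(t[0], t[1])] = (float(vals[0]), float(vals[1]))
            elif section == "ANGLE":
                t, vals = _split_types(line, 3)
                p.angle[(t[0], t[1], t[2])] = (float(vals[0]),
                                               float(vals[1]))
            elif section == "DIHE":
                t, vals = _split_types(line, 4)
                idivf, pk, phase, pn = (float(vals[0]), float(vals[1]),
                                        float(vals[2]), float(vals[3]))
                term = TorsionTerm(v_half=pk / idivf, phase=phase * DEG,
                                   periodicity=abs(int(round(pn))))
                p.torsion.setdefault(tuple(t), []).append(term)
            elif section == "NONBON":
                t, vals = _split_types(line, 1)
                p.vdw[t[0]] = (float(vals[0]), float(vals[1]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse parameter line {line!r}") from exc
    return p


def _split_types(line: str, n_types: int) -> tuple[list[str], list[str]]:
    """Split ``a -b -c   1.0  2.0`` into type names and numeric fields."""
    if n_types > 1:
        # type field may contain '-' separators with optional padding
        head = line[: _type_field_end(line, n_types)]
        types = [t.strip() for t in head.split("-")]
        rest = line[_type_field_end(line, n_types):].split()
    else:
        parts = line.split()
        types, rest = [parts[0]], parts[1:]
    if len(types) != n_types:
        raise ValueError(line)
    return types, rest


def _type_field_end(line: str, n_types: int) -> int:
    dashes = 0
    for pos, ch in enumerate(line):
        if ch == "-":
            dashes += 1
        elif ch.isspace() and dashes == n_types - 1 and pos > 0:
            # end of the last type token
            if line[:pos].replace("-", " ").split():
                tokens = line[:pos].split("-")
                if len(tokens) == n_types and tokens[-1].strip():
                    return pos
    raise ValueError(f"cannot locate type field in {line!r}")


def load_bundled_parameters() -> FFParameters:
    text = (resources.files("molsample.data") / "minimal_gaff.frcmod"
            ).read_text()
    return read_frcmod(text, is_text=True)


def load_sybyl_map() -> dict[str, str]:
    text = (resources.files("molsample.data") / "sybyl_to_gaff.tsv").read_text()
    out = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sybyl, gaff = line.split()
        out[sybyl] = gaff
    return out


# ---------------------------------------------------------------------------
# parameter schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterScheme:
    """Weights of the augmented nonbonded energy function.

    ``epsilon`` is the slope of the distance-dependent dielectric
    (eps_r = epsilon * d); ``desolv_factor`` the sigma of the pairwise
    desolvation term; ``K_polarized/K_arom/K_aliph`` the hydrophobic contact
    constants per carbon class.
    """

    name: str
    epsilon: float
    desolv_factor: float
    minq_to_desolv: float
    hbond_bonus: float
    repulsive_factor: float
    vicinal_weight: float
    desolv_scale_ion: float
    desolv_scale_hb: float
    K_polarized: float
    K_arom: float
    K_aliph: float
    coulomb14_scale: float = 1.0  # AMBER-style 1/1.2 scaling available, off by default

    def hydrophobic_constant(self, hclass: str) -> float:
        return {"polarized": self.K_polarized, "aromatic": self.K_arom,
                "aliphatic": self.K_aliph}[hclass]

    def with_triplet(self, k_polarized: float, k_arom: float,
                     k_aliph: float) -> "ParameterScheme":
        return replace(self, name="custom", K_polarized=k_polarized,
                       K_arom=k_arom, K_aliph=k_aliph)


_SCHEMES = {
    "core": ParameterScheme(
        name="core", epsilon=2.0, desolv_factor=0.0, minq_to_desolv=0.0,
        hbond_bonus=0.0, repulsive_factor=1.00, vicinal_weight=0.5,
        desolv_scale_ion=1.0, desolv_scale_hb=1.0,
        K_polarized=0.0, K_arom=0.0, K_aliph=0.0),
    "preliminary": ParameterScheme(
        name="preliminary", epsilon=4.0, desolv_factor=0.1,
        minq_to_desolv=0.125, hbond_bonus=2.0, repulsive_factor=0.75,
        vicinal_weight=0.033, desolv_scale_ion=1.0, desolv_scale_hb=1.0,
        K_polarized=0.1, K_arom=0.1, K_aliph=0.1),
    "fit": ParameterScheme(
        name="fit", epsilon=4.0, desolv_factor=0.1, minq_to_desolv=0.125,
        hbond_bonus=2.0, repulsive_factor=0.75, vicinal_weight=0.033,
        desolv_scale_ion=0.1, desolv_scale_hb=0.1,
        K_polarized=0.01, K_arom=0.15, K_aliph=0.15),
}


def get_scheme(name: str) -> ParameterScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown parameter scheme {name!r}; "
                       f"choose from {sorted(_SCHEMES)}") from None


def scheme_from_file(path: str) -> ParameterScheme:
    """Read a key=value scheme file (keys as in :class:`ParameterScheme`)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, val = (x.strip() for x in line.split("=", 1))
            values[key] = float(val)
    base = _SCHEMES["fit"]
    fields = {f: values.get(f, getattr(base, f))
              for f in base.__dataclass_fields__ if f != "name"}
    return ParameterScheme(name="custom", **fields)


# Discrete grid of hydrophobic constants used by the rescoring scan.
K_SCAN_VALUES = (0.0, 0.010, 0.025, 0.050, 0.075, 0.100,
                 0.150, 0.200, 0.250, 0.300)
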