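"""Chemical templates for the 20 standard amino acids and their dipeptides.

Every fragment handled by this toolkit is normalized ("completed") to the
neutral free-molecule form:

* single residues are free amino acids — NH2 amine, COOH carboxylic acid
  (atoms ``OXT``/``HXT``), neutral side chains;
* dipeptides are free dipeptides — NH2 ... CO-NH ... COOH, i.e. the
  condensation of two free amino acids through one peptide bond (net loss of
  one water: one O and two H);
* histidine is fixed to the neutral tautomer with the Nd (``ND1``) atom
  protonated and Ne (``NE2``) bare;
* cysteine always carries its thiol hydrogen (disulfide partners are treated
  as dissociated).

Templates carry, per atom, internal coordinates (bond length, bond angle,
torsion plus the three reference atoms) sufficient to rebuild Cartesian
coordinates, the covalent bond list (tree bonds plus explicit ring closures)
and the named rotatable torsions (backbone analogues and side-chain chi
angles).  Bond lengths and angles are conventional ideal values for neutral
amino acids; ring internal coordinates are chosen so that closure bonds come
out at standard lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import bond_angle, dihedral_angle, place_atom

__all__ = [
    "AtomSpec",
    "ResidueTemplate",
    "ALL_CODES",
    "ONE_LETTER",
    "get_template",
    "atom_count",
    "dipeptide_template",
    "build_coordinates",
    "read_torsion",
    "molecular_formula",
]

#: the 20 standard 3-letter codes, alphabetical
ALL_CODES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: maximum covalent connectivity per element in the neutral molecules handled
MAX_DEGREE = {"C": 4, "N": 3, "O": 2, "S": 2, "H": 1}


@dataclass(frozen=True)
class AtomSpec:
    """One template atom with its internal-coordinate definition.

    ``parent``/``aref``/``dref`` are indices of earlier atoms in the template
    order (None only for the first three atoms, which seed the frame).
    ``torsion`` is the default value of the X-parent-aref-dref torsion.
    """

    name: str
    element: str
    parent: int | None
    aref: int | None
    dref: int | None
    length: float
    angle: float
    torsion: float
    res_index: int = 0

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class ResidueTemplate:
    code: str
    one_letter: str
    atoms: tuple[AtomSpec, ...]
    bonds: tuple[tuple[int, int], ...]
    rotatable_dihedrals: dict[str, int]
    n_residues: int = 1

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.atoms) if a.is_heavy)

    def index_of(self, name: str, res_index: int = 0) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name and a.res_index == res_index:
                return i
        raise KeyError(f"no atom {name!r} (residue {res_index}) in {self.code}")


# ---------------------------------------------------------------------------
# Template authoring
# ---------------------------------------------------------------------------
# Side-chain rows: (name, element, parent, aref, dref, length, angle, torsion)
# optionally followed by a rotatable-torsion name.  References are atom names
# resolved within the residue.  "h2"/"h3" helpers expand methylene / methyl
# hydrogens.


def _h2(name_a, name_b, parent, aref, dref, length=1.09, angle=109.4):
    """Two geminal hydrogens at +/-120 degrees from the heavy sibling dref."""
    return [
        (name_a, "H", parent, aref, dref, length, angle, 120.0),
        (name_b, "H", parent, aref, dref, length, angle, -120.0),
    ]


def _h3(n1, n2, n3, parent, aref, dref, length=1.09, angle=109.8):
    """Staggered methyl: first H anti to dref, siblings chained off it."""
    return [
        (n1, "H", parent, aref, dref, length, angle, 180.0),
        (n2, "H", parent, aref, n1, length, angle, 120.0),
        (n3, "H", parent, aref, n1, length, angle, -120.0),
    ]


_SIDE = {
    "GLY": dict(heavy=[], closures=[], hyd=[]),
    "ALA": dict(
        heavy=[("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0)],
        closures=[],
        hyd=_h3("HB1", "HB2", "HB3", "CB", "CA", "N"),
    ),
    "VAL": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.540, 111.5, 122.0),
            ("CG1", "C", "CB", "CA", "N", 1.530, 110.7, 175.0, "chi1"),
            ("CG2", "C", "CB", "CA", "CG1", 1.530, 110.7, 122.0),
        ],
        closures=[],
        hyd=[("HB", "H", "CB", "CA", "CG1", 1.09, 108.0, -119.0)]
        + _h3("HG11", "HG12", "HG13", "CG1", "CB", "CA")
        + _h3("HG21", "HG22", "HG23", "CG2", "CB", "CA"),
    ),
    "LEU": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.530, 116.3, 180.0, "chi1"),
            ("CD1", "C", "CG", "CB", "CA", 1.530, 110.7, 180.0, "chi2"),
            ("CD2", "C", "CG", "CB", "CD1", 1.530, 110.7, 122.0),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [("HG", "H", "CG", "CB", "CD1", 1.09, 108.0, -119.0)]
        + _h3("HD11", "HD12", "HD13", "CD1", "CG", "CB")
        + _h3("HD21", "HD22", "HD23", "CD2", "CG", "CB"),
    ),
    "ILE": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.540, 111.5, 122.0),
            ("CG1", "C", "CB", "CA", "N", 1.530, 110.4, 175.0, "chi1"),
            ("CG2", "C", "CB", "CA", "CG1", 1.530, 110.5, -122.0),
            ("CD1", "C", "CG1", "CB", "CA", 1.530, 113.8, 180.0, "chi2"),
        ],
        closures=[],
        hyd=[("HB", "H", "CB", "CA", "CG1", 1.09, 108.0, 119.0)]
        + _h2("HG12", "HG13", "CG1", "CB", "CD1")
        + _h3("HG21", "HG22", "HG23", "CG2", "CB", "CA")
        + _h3("HD11", "HD12", "HD13", "CD1", "CG1", "CB"),
    ),
    "PRO": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 103.0, 120.0),
            ("CG", "C", "CB", "CA", "N", 1.500, 104.5, -31.0),
            ("CD", "C", "CG", "CB", "CA", 1.510, 105.5, 36.0),
        ],
        closures=[("CD", "N")],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + _h2("HG2", "HG3", "CG", "CB", "CD")
        + _h2("HD2", "HD3", "CD", "N", "CA", 1.09, 110.0),
    ),
    "MET": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.530, 114.1, 180.0, "chi1"),
            ("SD", "S", "CG", "CB", "CA", 1.810, 112.7, 180.0, "chi2"),
            ("CE", "C", "SD", "CG", "CB", 1.790, 100.2, 180.0, "chi3"),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + _h2("HG2", "HG3", "CG", "CB", "SD")
        + _h3("HE1", "HE2", "HE3", "CE", "SD", "CG"),
    ),
    "PHE": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.510, 113.8, 180.0, "chi1"),
            ("CD1", "C", "CG", "CB", "CA", 1.390, 120.8, 90.0, "chi2"),
            ("CD2", "C", "CG", "CD1", "CB", 1.390, 120.0, 180.0),
            ("CE1", "C", "CD1", "CG", "CD2", 1.390, 120.0, 0.0),
            ("CE2", "C", "CD2", "CG", "CD1", 1.390, 120.0, 0.0),
            ("CZ", "C", "CE1", "CD1", "CG", 1.390, 120.0, 0.0),
        ],
        closures=[("CZ", "CE2")],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [
            ("HD1", "H", "CD1", "CG", "CD2", 1.08, 120.0, 180.0),
            ("HD2", "H", "CD2", "CG", "CD1", 1.08, 120.0, 180.0),
            ("HE1", "H", "CE1", "CD1", "CG", 1.08, 120.0, 180.0),
            ("HE2", "H", "CE2", "CD2", "CG", 1.08, 120.0, 180.0),
            ("HZ", "H", "CZ", "CE1", "CD1", 1.08, 120.0, 180.0),
        ],
    ),
    "TYR": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.510, 113.8, 180.0, "chi1"),
            ("CD1", "C", "CG", "CB", "CA", 1.390, 120.8, 90.0, "chi2"),
            ("CD2", "C", "CG", "CD1", "CB", 1.390, 120.0, 180.0),
            ("CE1", "C", "CD1", "CG", "CD2", 1.390, 120.0, 0.0),
            ("CE2", "C", "CD2", "CG", "CD1", 1.390, 120.0, 0.0),
            ("CZ", "C", "CE1", "CD1", "CG", 1.390, 120.0, 0.0),
            ("OH", "O", "CZ", "CE1", "CD1", 1.380, 120.0, 180.0),
        ],
        closures=[("CZ", "CE2")],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [
            ("HD1", "H", "CD1", "CG", "CD2", 1.08, 120.0, 180.0),
            ("HD2", "H", "CD2", "CG", "CD1", 1.08, 120.0, 180.0),
            ("HE1", "H", "CE1", "CD1", "CG", 1.08, 120.0, 180.0),
            ("HE2", "H", "CE2", "CD2", "CG", 1.08, 120.0, 180.0),
            ("HH", "H", "OH", "CZ", "CE1", 0.96, 110.0, 180.0),
        ],
    ),
    "TRP": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.500, 114.0, 180.0, "chi1"),
            ("CD1", "C", "CG", "CB", "CA", 1.370, 126.9, 90.0, "chi2"),
            ("CD2", "C", "CG", "CD1", "CB", 1.430, 106.3, 180.0),
            ("NE1", "N", "CD1", "CG", "CD2", 1.380, 110.2, 0.0),
            ("CE2", "C", "NE1", "CD1", "CG", 1.370, 108.9, 0.0),
            ("CE3", "C", "CD2", "CG", "CD1", 1.400, 133.9, 180.0),
            ("CZ3", "C", "CE3", "CD2", "CG", 1.390, 118.8, 180.0),
            ("CH2", "C", "CZ3", "CE3", "CD2", 1.370, 121.2, 0.0),
            ("CZ2", "C", "CH2", "CZ3", "CE3", 1.400, 121.5, 0.0),
        ],
        closures=[("CE2", "CD2"), ("CZ2", "CE2")],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [
            ("HD1", "H", "CD1", "CG", "CD2", 1.08, 126.0, 180.0),
            ("HE1", "H", "NE1", "CD1", "CG", 1.01, 125.0, 180.0),
            ("HE3", "H", "CE3", "CD2", "CG", 1.08, 120.0, 0.0),
            ("HZ3", "H", "CZ3", "CE3", "CD2", 1.08, 120.0, 180.0),
            ("HH2", "H", "CH2", "CZ3", "CE3", 1.08, 120.0, 180.0),
            ("HZ2", "H", "CZ2", "CH2", "CZ3", 1.08, 120.0, 180.0),
        ],
    ),
    "SER": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("OG", "O", "CB", "CA", "N", 1.410, 110.8, 180.0, "chi1"),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "OG")
        + [("HG", "H", "OG", "CB", "CA", 0.96, 108.5, 180.0)],
    ),
    "THR": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.540, 111.5, 122.0),
            ("OG1", "O", "CB", "CA", "N", 1.410, 109.6, 175.0, "chi1"),
            ("CG2", "C", "CB", "CA", "OG1", 1.530, 110.5, -122.0),
        ],
        closures=[],
        hyd=[
            ("HB", "H", "CB", "CA", "OG1", 1.09, 108.0, 122.0),
            ("HG1", "H", "OG1", "CB", "CA", 0.96, 108.5, 180.0),
        ]
        + _h3("HG21", "HG22", "HG23", "CG2", "CB", "CA"),
    ),
    "CYS": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("SG", "S", "CB", "CA", "N", 1.810, 113.4, 180.0, "chi1"),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "SG")
        + [("HG", "H", "SG", "CB", "CA", 1.34, 96.0, 180.0)],
    ),
    "ASN": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.520, 112.6, 180.0, "chi1"),
            ("OD1", "O", "CG", "CB", "CA", 1.230, 120.8, -60.0, "chi2"),
            ("ND2", "N", "CG", "CB", "OD1", 1.330, 116.4, 180.0),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [
            ("HD21", "H", "ND2", "CG", "OD1", 1.01, 120.0, 180.0),
            ("HD22", "H", "ND2", "CG", "OD1", 1.01, 120.0, 0.0),
        ],
    ),
    "ASP": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.520, 112.6, 180.0, "chi1"),
            ("OD1", "O", "CG", "CB", "CA", 1.230, 120.8, -60.0, "chi2"),
            ("OD2", "O", "CG", "CB", "OD1", 1.340, 117.0, 180.0),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [("HD2", "H", "OD2", "CG", "OD1", 0.96, 107.0, 0.0)],
    ),
    "GLN": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.530, 114.1, 180.0, "chi1"),
            ("CD", "C", "CG", "CB", "CA", 1.520, 112.6, 180.0, "chi2"),
            ("OE1", "O", "CD", "CG", "CB", 1.230, 120.8, -60.0, "chi3"),
            ("NE2", "N", "CD", "CG", "OE1", 1.330, 116.4, 180.0),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + _h2("HG2", "HG3", "CG", "CB", "CD")
        + [
            ("HE21", "H", "NE2", "CD", "OE1", 1.01, 120.0, 180.0),
            ("HE22", "H", "NE2", "CD", "OE1", 1.01, 120.0, 0.0),
        ],
    ),
    "GLU": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.530, 114.1, 180.0, "chi1"),
            ("CD", "C", "CG", "CB", "CA", 1.520, 112.6, 180.0, "chi2"),
            ("OE1", "O", "CD", "CG", "CB", 1.230, 120.8, -60.0, "chi3"),
            ("OE2", "O", "CD", "CG", "OE1", 1.340, 117.0, 180.0),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + _h2("HG2", "HG3", "CG", "CB", "CD")
        + [("HE2", "H", "OE2", "CD", "OE1", 0.96, 107.0, 0.0)],
    ),
    "LYS": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.530, 114.1, 180.0, "chi1"),
            ("CD", "C", "CG", "CB", "CA", 1.530, 111.3, 180.0, "chi2"),
            ("CE", "C", "CD", "CG", "CB", 1.530, 111.3, 180.0, "chi3"),
            ("NZ", "N", "CE", "CD", "CG", 1.470, 111.9, 180.0, "chi4"),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + _h2("HG2", "HG3", "CG", "CB", "CD")
        + _h2("HD2", "HD3", "CD", "CG", "CE")
        + _h2("HE2", "HE3", "CE", "CD", "NZ")
        + [
            ("HZ1", "H", "NZ", "CE", "CD", 1.01, 109.5, 60.0),
            ("HZ2", "H", "NZ", "CE", "HZ1", 1.01, 109.5, 120.0),
        ],
    ),
    "ARG": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.530, 114.1, 180.0, "chi1"),
            ("CD", "C", "CG", "CB", "CA", 1.530, 111.3, 180.0, "chi2"),
            ("NE", "N", "CD", "CG", "CB", 1.460, 111.5, 180.0, "chi3"),
            ("CZ", "C", "NE", "CD", "CG", 1.330, 124.0, 180.0, "chi4"),
            ("NH1", "N", "CZ", "NE", "CD", 1.370, 120.0, 0.0),
            ("NH2", "N", "CZ", "NE", "NH1", 1.280, 120.0, 180.0),
        ],
        closures=[],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + _h2("HG2", "HG3", "CG", "CB", "CD")
        + _h2("HD2", "HD3", "CD", "CG", "NE")
        + [
            ("HE", "H", "NE", "CZ", "NH1", 1.01, 119.0, 180.0),
            ("HH11", "H", "NH1", "CZ", "NE", 1.01, 120.0, 0.0),
            ("HH12", "H", "NH1", "CZ", "NE", 1.01, 120.0, 180.0),
            ("HH21", "H", "NH2", "CZ", "NE", 1.01, 112.0, 180.0),
        ],
    ),
    "HIS": dict(
        heavy=[
            ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.0),
            ("CG", "C", "CB", "CA", "N", 1.500, 113.8, 180.0, "chi1"),
            ("ND1", "N", "CG", "CB", "CA", 1.380, 122.7, -75.0, "chi2"),
            ("CD2", "C", "CG", "ND1", "CB", 1.360, 109.3, 180.0),
            ("CE1", "C", "ND1", "CG", "CD2", 1.320, 109.0, 0.0),
            ("NE2", "N", "CE1", "ND1", "CG", 1.340, 111.7, 0.0),
        ],
        closures=[("NE2", "CD2")],
        hyd=_h2("HB2", "HB3", "CB", "CA", "CG")
        + [
            ("HD1", "H", "ND1", "CG", "CD2", 1.01, 126.0, 180.0),
            ("HD2", "H", "CD2", "CG", "ND1", 1.08, 128.0, 180.0),
            ("HE1", "H", "CE1", "ND1", "CG", 1.08, 124.0, 180.0),
        ],
    ),
}


class _Builder:
    def __init__(self):
        self.atoms: list[AtomSpec] = []
        self.bonds: list[tuple[int, int]] = []
        self.rot: dict[str, int] = {}
        self._index: dict[tuple[str, int], int] = {}

    def idx(self, name, res=0):
        return self._index[(name, res)]

    def _ref(self, ref, res):
        if ref is None or isinstance(ref, int):
            return ref
        if isinstance(ref, tuple):
            return self.idx(ref[0], ref[1])
        return self.idx(ref, res)

    def add(self, name, element, parent=None, aref=None, dref=None,
            length=0.0, angle=0.0, torsion=0.0, rot=None, res=0, bond=True):
        i = len(self.atoms)
        p = self._ref(parent, res)
        a = self._ref(aref, res)
        d = self._ref(dref, res)
        self.atoms.append(AtomSpec(name, element, p, a, d, length, angle,
                                   torsion, res))
        self._index[(name, res)] = i
        if p is not None and bond:
            self.bonds.append((p, i))
        if rot:
            self.rot[rot] = i
        return i

    def add_row(self, row, res=0, ref_res=None):
        ref_res = res if ref_res is None else ref_res
        name, element, p, a, d, length, angle, torsion = row[:8]
        rot = row[8] if len(row) > 8 else None
        self.add(name, element, (p, res), (a, res), (d, res), length, angle,
                 torsion, rot=rot, res=res)

    def close(self, name_a, name_b, res_a=0, res_b=0):
        self.bonds.append((self.idx(name_a, res_a), self.idx(name_b, res_b)))


def _build_single(code: str) -> ResidueTemplate:
    side = _SIDE[code]
    b = _Builder()
    # backbone heavies
    b.add("N", "N")
    b.add("CA", "C", "N", length=1.458)
    b.add("C", "C", "CA", "N", length=1.525, angle=111.0)
    b.add("O", "O", "C", "CA", "N", 1.231, 120.5, -45.0, rot="psi")
    b.add("OXT", "O", "C", "CA", "O", 1.340, 116.0, 180.0)
    for row in side["heavy"]:
        b.add(*row[:5], *row[5:8], rot=(row[8] if len(row) > 8 else None))
    for a_name, b_name in side["closures"]:
        b.close(a_name, b_name)
    # hydrogens
    if code == "PRO":
        b.add("H", "H", "N", "CA", "CD", 1.01, 110.0, 120.0)
        b.add("HA", "H", "CA", "N", "C", 1.09, 108.5, -118.0)
    elif code == "GLY":
        b.add("H1", "H", "N", "CA", "C", 1.01, 109.5, -60.0, rot="nh2")
        b.add("H2", "H", "N", "CA", "H1", 1.01, 109.5, 120.0)
        b.add("HA2", "H", "CA", "N", "C", 1.09, 109.0, 118.0)
        b.add("HA3", "H", "CA", "N", "C", 1.09, 109.0, -122.0)
    else:
        b.add("H1", "H", "N", "CA", "C", 1.01, 109.5, -60.0, rot="nh2")
        b.add("H2", "H", "N", "CA", "H1", 1.01, 109.5, 120.0)
        b.add("HA", "H", "CA", "N", "C", 1.09, 108.5, -118.0)
    for row in side["hyd"]:
        b.add(*row[:5], *row[5:8])
    b.add("HXT", "H", "OXT", "C", "O", 0.96, 107.0, 0.0)
    return ResidueTemplate(code, ONE_LETTER[code], tuple(b.atoms),
                           tuple(b.bonds), dict(b.rot), 1)


def _normalize(code: str) -> str:
    c = code.upper().strip()
    if c not in _SIDE:
        raise KeyError(f"unknown residue code: {code!r}")
    return c


@lru_cache(maxsize=None)
def get_template(code: str) -> ResidueTemplate:
    """Template of the neutral free amino acid for a 3-letter code.

    Case-insensitive; raises ``KeyError`` for non-standard codes.
    """
    return _build_single(_normalize(code))


def atom_count(code: str) -> int:
    """Number of atoms (hydrogens included) of the completed fragment.

    Accepts a 3-letter single-residue code or a 6-letter dipeptide code.
    """
    c = code.upper().strip()
    if len(c) == 6:
        return len(dipeptide_template(c[:3], c[3:]).atoms)
    return len(get_template(c).atoms)


@lru_cache(maxsize=None)
def dipeptide_template(code1: str, code2: str) -> ResidueTemplate:
    """Free-dipeptide template: condensation through one peptide bond.

    The atom count is ``atom_count(code1) + atom_count(code2) - 3`` (loss of
    one water equivalent).  Torsion names from the two residues are suffixed
    ``_1``/``_2``; the linkage adds ``psi1`` (about CA1-C1), the fixed trans
    ``omega`` and ``phi2`` (about N2-CA2).
    """
    c1, c2 = _normalize(code1), _normalize(code2)
    s1, s2 = _SIDE[c1], _SIDE[c2]
    b = _Builder()
    # residue 1 backbone + side chain (no O/OXT yet: the carbonyl O is placed
    # after the peptide nitrogen so that psi1 has a single carrier atom)
    b.add("N", "N", res=0)
    b.add("CA", "C", ("N", 0), length=1.458, res=0)
    b.add("C", "C", ("CA", 0), ("N", 0), length=1.525, angle=111.0, res=0)
    for row in s1["heavy"]:
        rot = (row[8] + "_1") if len(row) > 8 else None
        b.add(row[0], row[1], (row[2], 0), (row[3], 0), (row[4], 0),
              row[5], row[6], row[7], rot=rot, res=0)
    for a_name, b_name in s1["closures"]:
        b.close(a_name, b_name, 0, 0)
    # peptide linkage
    b.add("N", "N", ("C", 0), ("CA", 0), ("N", 0), 1.335, 116.2, -90.0,
          rot="psi1", res=1)
    b.add("O", "O", ("C", 0), ("CA", 0), ("N", 1), 1.231, 120.5, 180.0, res=0)
    b.add("CA", "C", ("N", 1), ("C", 0), ("CA", 0), 1.458, 121.7, 180.0,
          rot="omega", res=1)
    if c2 == "PRO":
        # proline's phi is constrained by its ring: the carbonyl carbon of
        # the preceding residue must stay in the amide plane opposite CD
        b.add("C", "C", ("CA", 1), ("N", 1), ("C", 0), 1.525, 111.0, 75.0,
              res=1)
    else:
        b.add("C", "C", ("CA", 1), ("N", 1), ("C", 0), 1.525, 111.0, -120.0,
              rot="phi2", res=1)
    # residue 2 side chain
    for row in s2["heavy"]:
        rot = (row[8] + "_2") if len(row) > 8 else None
        b.add(row[0], row[1], (row[2], 1), (row[3], 1), (row[4], 1),
              row[5], row[6], row[7], rot=rot, res=1)
    for a_name, b_name in s2["closures"]:
        b.close(a_name, b_name, 1, 1)
    b.add("O", "O", ("C", 1), ("CA", 1), ("N", 1), 1.231, 120.5, -45.0,
          rot="psi2", res=1)
    b.add("OXT", "O", ("C", 1), ("CA", 1), ("O", 1), 1.340, 116.0, 180.0,
          res=1)
    # hydrogens, residue 1 (free amine)
    if c1 == "PRO":
        b.add("H", "H", ("N", 0), ("CA", 0), ("CD", 0), 1.01, 110.0, 120.0,
              res=0)
        b.add("HA", "H", ("CA", 0), ("N", 0), ("C", 0), 1.09, 108.5, -118.0,
              res=0)
    elif c1 == "GLY":
        b.add("H1", "H", ("N", 0), ("CA", 0), ("C", 0), 1.01, 109.5, -60.0,
              rot="nh2", res=0)
        b.add("H2", "H", ("N", 0), ("CA", 0), ("H1", 0), 1.01, 109.5, 120.0,
              res=0)
        b.add("HA2", "H", ("CA", 0), ("N", 0), ("C", 0), 1.09, 109.0, 118.0,
              res=0)
        b.add("HA3", "H", ("CA", 0), ("N", 0), ("C", 0), 1.09, 109.0, -122.0,
              res=0)
    else:
        b.add("H1", "H", ("N", 0), ("CA", 0), ("C", 0), 1.01, 109.5, -60.0,
              rot="nh2", res=0)
        b.add("H2", "H", ("N", 0), ("CA", 0), ("H1", 0), 1.01, 109.5, 120.0,
              res=0)
        b.add("HA", "H", ("CA", 0), ("N", 0), ("C", 0), 1.09, 108.5, -118.0,
              res=0)
    for row in s1["hyd"]:
        b.add(row[0], row[1], (row[2], 0), (row[3], 0), (row[4], 0),
              row[5], row[6], row[7], res=0)
    # hydrogens, residue 2 (amide N-H unless proline)
    if c2 != "PRO":
        b.add("H", "H", ("N", 1), ("C", 0), ("O", 0), 1.01, 119.0, 180.0,
              res=1)
    if c2 == "GLY":
        b.add("HA2", "H", ("CA", 1), ("N", 1), ("C", 1), 1.09, 109.0, 118.0,
              res=1)
        b.add("HA3", "H", ("CA", 1), ("N", 1), ("C", 1), 1.09, 109.0, -122.0,
              res=1)
    else:
        b.add("HA", "H", ("CA", 1), ("N", 1), ("C", 1), 1.09, 108.5, -118.0,
              res=1)
    for row in s2["hyd"]:
        b.add(row[0], row[1], (row[2], 1), (row[3], 1), (row[4], 1),
              row[5], row[6], row[7], res=1)
    b.add("HXT", "H", ("OXT", 1), ("C", 1), ("O", 1), 0.96, 107.0, 0.0, res=1)
    return ResidueTemplate(c1 + c2, ONE_LETTER[c1] + ONE_LETTER[c2],
                           tuple(b.atoms), tuple(b.bonds), dict(b.rot), 2)


# ---------------------------------------------------------------------------
# Cartesian reconstruction
# ---------------------------------------------------------------------------

def build_coordinates(template: ResidueTemplate,
                      torsions: dict[str, float] | None = None) -> np.ndarray:
    """Rebuild Cartesian coordinates (n_atoms, 3) from internal coordinates.

    ``torsions`` overrides the default values of named rotatable torsions.
    """
    overrides: dict[int, float] = {}
    if torsions:
        for name, value in torsions.items():
            if name not in template.rotatable_dihedrals:
                raise KeyError(
                    f"{template.code} has no rotatable torsion {name!r}")
            overrides[template.rotatable_dihedrals[name]] = float(value)
    coords = np.zeros((len(template.atoms), 3))
    for i, atom in enumerate(template.atoms):
        if i == 0:
            continue
        if i == 1:
            coords[1] = coords[atom.parent] + np.array([atom.length, 0.0, 0.0])
            continue
        if i == 2:
            p = coords[atom.parent]
            v = coords[atom.aref] - p
            v /= np.linalg.norm(v)
            theta = np.deg2rad(atom.angle)
            coords[2] = p + atom.length * (np.cos(theta) * v
                                           + np.sin(theta) * np.array([0.0, 1.0, 0.0]))
            continue
        torsion = overrides.get(i, atom.torsion)
        coords[i] = place_atom(coords[atom.parent], coords[atom.aref],
                               coords[atom.dref], atom.length, atom.angle,
                               torsion)
    return coords


def read_torsion(template: ResidueTemplate, coords: np.ndarray,
                 name: str) -> float:
    """Measure a named rotatable torsion (degrees) from coordinates."""
    i = template.rotatable_dihedrals[name]
    a = template.atoms[i]
    return dihedral_angle(coords[i], coords[a.parent], coords[a.aref],
                          coords[a.dref])


def measure_internal(template: ResidueTemplate, coords: np.ndarray):
    """Per-atom (length, angle, torsion) measured from coordinates.

    Entries for the first three atoms contain NaN where undefined; used to
    verify the internal->Cartesian->internal round trip.
    """
    out = np.full((len(template.atoms), 3), np.nan)
    for i, a in enumerate(template.atoms):
        if a.parent is not None:
            out[i, 0] = np.linalg.norm(coords[i] - coords[a.parent])
        if a.aref is not None:
            out[i, 1] = bond_angle(coords[i], coords[a.parent], coords[a.aref])
        if a.dref is not None:
            out[i, 2] = dihedral_angle(coords[i], coords[a.parent],
                                       coords[a.aref], coords[a.dref])
    return out


def molecular_formula(template: ResidueTemplate) -> dict[str, int]:
    """Element counts of the template, e.g. ``{"C": 2, "H": 5, ...}``."""
    counts: dict[str, int] = {}
    for a in template.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
    return counts
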