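"""Harvest single-residue and dipeptide fragments from PDB structures.

The pipeline is: parse a PDB file into a light chain/residue model, excise
every standard residue (or every covalently continuous residue pair), then
normalize each raw heavy-atom fragment to the completed template form by
rebuilding hydrogens and terminal atoms from template internal coordinates
anchored on the existing heavy atoms.  Input hydrogens are always discarded
and rebuilt, which guarantees homogeneity across sources; heavy-atom
coordinates are never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import chemistry
from .fragments import Fragment
from .geometry import place_atom

__all__ = [
    "ParsedStructure",
    "parse_structure",
    "extract_single_fragments",
    "extract_dual_fragments",
    "complete_fragment",
    "extract_from_paths",
]

log = logging.getLogger(__name__)

#: peptide-bond continuity criterion: C(i)-N(i+1) distance, Angstrom
PEPTIDE_BOND_CUTOFF = 1.7


@dataclass
class ResidueRecord:
    name: str
    seqid: str  # residue number + insertion code
    atoms: dict[str, np.ndarray]  # heavy-atom name -> xyz
    elements: dict[str, str]


@dataclass
class ParsedStructure:
    """Chains (in file order) of residues with heavy-atom records."""

    source_id: str
    chains: list[tuple[str, list[ResidueRecord]]] = field(default_factory=list)


def _normalize_atom_name(res_name: str, atom_name: str) -> str:
    # a few legacy aliases seen in the wild
    if res_name == "ILE" and atom_name == "CD":
        return "CD1"
    return atom_name


def parse_structure(pdb_text: str, source_id: str = "") -> ParsedStructure:
    """Parse PDB-format text into chains of residues with heavy atoms.

    Alternate locations are resolved to a single conformer (first/blank
    altloc); hydrogens are dropped (they are rebuilt during completion);
    insertion codes are preserved in the residue id.  Raises ValueError on
    unreadable content or when no ATOM/HETATM records survive.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable PDB content: {exc}") from exc
    structure.remove_alternative_conformations()
    structure.remove_hydrogens()
    parsed = ParsedStructure(source_id or structure.name or "pdb")
    if len(structure) == 0:
        raise ValueError("empty model: no coordinates in input")
    model = structure[0]
    for chain in model:
        residues = []
        for res in chain:
            atoms: dict[str, np.ndarray] = {}
            elements: dict[str, str] = {}
            for atom in res:
                name = _normalize_atom_name(res.name, atom.name)
                if name in atoms:
                    continue  # duplicate after altloc collapse
                atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                elements[name] = atom.element.name
            seqid = f"{res.seqid.num}{res.seqid.icode}".strip()
            residues.append(ResidueRecord(res.name, seqid, atoms, elements))
        parsed.chains.append((chain.name, residues))
    if not any(res.atoms for _, residues in parsed.chains for res in residues):
        raise ValueError("empty model: no atom records parsed")
    return parsed


def _template_heavy_names(template: chemistry.ResidueTemplate):
    return {(a.name, a.res_index) for a in template.atoms if a.is_heavy}


def complete_fragment(label: str,
                      heavy_atoms: dict[tuple[str, int], np.ndarray],
                      source_id: str = "") -> Fragment:
    """Build the completed Fragment from raw heavy atoms.

    ``heavy_atoms`` maps (atom name, residue index) to coordinates; residue
    index is 0 for singles, 0/1 for dipeptides.  The terminal ``OXT`` (and
    its hydrogen) may be absent in the input — it is rebuilt like the
    hydrogens.  Any other mismatch against the template heavy-atom set is
    rejected, naming the offending atoms.  Heavy-atom coordinates pass
    through bit-identically; every missing atom is placed from template
    internal coordinates anchored on already-placed atoms.
    """
    if len(label) == 6:
        template = chemistry.dipeptide_template(label[:3], label[3:])
    else:
        template = chemistry.get_template(label)
    expected = _template_heavy_names(template)
    provided = set(heavy_atoms)
    optional = {("OXT", template.n_residues - 1)}
    missing = expected - provided - optional
    extra = provided - expected
    if missing or extra:
        parts = []
        if missing:
            parts.append("missing " + ", ".join(sorted(f"{n}/{r}" for n, r in missing)))
        if extra:
            parts.append("unexpected " + ", ".join(sorted(f"{n}/{r}" for n, r in extra)))
        raise ValueError(f"heavy-atom mismatch for {label}: " + "; ".join(parts))

    n = len(template.atoms)
    coords = np.zeros((n, 3))
    have = np.zeros(n, dtype=bool)
    for i, atom in enumerate(template.atoms):
        key = (atom.name, atom.res_index)
        if key in heavy_atoms:
            coords[i] = heavy_atoms[key]
            have[i] = True
    for i, atom in enumerate(template.atoms):
        if have[i]:
            continue
        if atom.parent is None or not (have[atom.parent] and have[atom.aref]
                                       and have[atom.dref]):
            raise ValueError(
                f"cannot anchor atom {atom.name} of {label}: reference "
                "atoms unavailable")
        coords[i] = place_atom(coords[atom.parent], coords[atom.aref],
                               coords[atom.dref], atom.length, atom.angle,
                               atom.torsion)
        have[i] = True
    return Fragment(
        label=template.code,
        atom_names=[a.name for a in template.atoms],
        elements=[a.element for a in template.atoms],
        coords=coords,
        source_id=source_id,
        n_residues=template.n_residues,
        res_indices=np.array([a.res_index for a in template.atoms]),
    )


def _raw_heavy(res: ResidueRecord, template, res_index_offset=0):
    """Heavy atoms of one residue keyed for the template; None if mismatched."""
    wanted = {name for name, r in _template_heavy_names(template)
              if r == res_index_offset}
    out = {}
    for name, xyz in res.atoms.items():
        if name in wanted:
            out[(name, res_index_offset)] = xyz
    return out


def _residue_complete(res: ResidueRecord, code: str, terminal: bool) -> bool:
    """Does the residue carry every heavy atom the single template expects?

    ``OXT`` is required only when completing as a standalone C-terminus is
    impossible — it is always optional, since completion rebuilds it.
    """
    template = chemistry.get_template(code)
    needed = {a.name for a in template.atoms if a.is_heavy} - {"OXT"}
    return needed <= set(res.atoms)


def extract_single_fragments(model: ParsedStructure,
                             skip_log: list | None = None) -> list[Fragment]:
    """One completed Fragment per standard residue with all heavy atoms.

    Non-standard residues and residues with missing side-chain heavy atoms
    are skipped (recorded in ``skip_log`` if given, and logged).
    """
    fragments = []
    skipped = skip_log if skip_log is not None else []
    for chain_name, residues in model.chains:
        for res in residues:
            sid = f"{model.source_id}:{chain_name}:{res.seqid}:{res.name}"
            if res.name not in chemistry.ONE_LETTER:
                skipped.append((sid, "non-standard residue"))
                continue
            if not _residue_complete(res, res.name, terminal=False):
                skipped.append((sid, "missing heavy atoms"))
                continue
            template = chemistry.get_template(res.name)
            raw = _raw_heavy(res, template)
            try:
                fragments.append(complete_fragment(res.name, raw, sid))
            except ValueError as exc:
                skipped.append((sid, str(exc)))
    if skipped:
        log.info("extract_single: skipped %d residues", len(skipped))
    return fragments


def _continuous(res_a: ResidueRecord, res_b: ResidueRecord) -> bool:
    if "C" not in res_a.atoms or "N" not in res_b.atoms:
        return False
    d = np.linalg.norm(res_a.atoms["C"] - res_b.atoms["N"])
    return d <= PEPTIDE_BOND_CUTOFF


def extract_dual_fragments(model: ParsedStructure,
                           skip_log: list | None = None) -> list[Fragment]:
    """One completed Fragment per covalently continuous residue pair.

    Pairs must be consecutive in the chain and joined by a peptide bond
    (C-N distance <= 1.7 A); the label is the N->C 6-letter concatenation.
    Chain breaks terminate pairing silently.
    """
    fragments = []
    skipped = skip_log if skip_log is not None else []
    for chain_name, residues in model.chains:
        for res_a, res_b in zip(residues, residues[1:]):
            sid = (f"{model.source_id}:{chain_name}:{res_a.seqid}-"
                   f"{res_b.seqid}:{res_a.name}{res_b.name}")
            if (res_a.name not in chemistry.ONE_LETTER
                    or res_b.name not in chemistry.ONE_LETTER):
                skipped.append((sid, "non-standard residue"))
                continue
            if not _continuous(res_a, res_b):
                continue  # chain break
            label = res_a.name + res_b.name
            template = chemistry.dipeptide_template(res_a.name, res_b.name)
            raw = {}
            for offset, res in ((0, res_a), (1, res_b)):
                wanted = {name for name, r in _template_heavy_names(template)
                          if r == offset}
                for name, xyz in res.atoms.items():
                    if name in wanted:
                        raw[(name, offset)] = xyz
            try:
                fragments.append(complete_fragment(label, raw, sid))
            except ValueError as exc:
                skipped.append((sid, str(exc)))
    if skipped:
        log.info("extract_dual: skipped %d pairs", len(skipped))
    return fragments


def extract_from_paths(paths, mode: str = "single"):
    """Extract fragments from PDB files; yields Fragment objects."""
    extract = {"single": extract_single_fragments,
               "dual": extract_dual_fragments}[mode]
    for path in paths:
        with open(path) as fh:
            model = parse_structure(fh.read(), source_id=str(path))
        yield from extract(model)
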