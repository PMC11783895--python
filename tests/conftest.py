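"""Shared fixtures: synthetic fragments, stores and PDB text builders."""

from __future__ import annotations

import numpy as np
import pytest

from flexfrag import chemistry
from flexfrag.generator import ConformerSpec, generate_class_ensemble
from flexfrag.fragments import Fragment


def make_fragment(code: str, seed: int = 0, **torsions) -> Fragment:
    """One ideal-geometry fragment of a class (default torsions unless given)."""
    if len(code) == 6:
        template = chemistry.dipeptide_template(code[:3], code[3:])
    else:
        template = chemistry.get_template(code)
    coords = chemistry.build_coordinates(template, torsions or None)
    return Fragment(
        label=template.code,
        atom_names=[a.name for a in template.atoms],
        elements=[a.element for a in template.atoms],
        coords=coords,
        source_id=f"fixture:{code}",
        n_residues=template.n_residues,
        res_indices=np.array([a.res_index for a in template.atoms]),
    )


def pdb_lines(residues, chain="A", start_serial=1):
    """PDB ATOM records for [(resname, resnum, [(name, elem, xyz), ...])]."""
    lines = []
    serial = start_serial
    for resname, resnum, atoms in residues:
        for name, elem, (x, y, z) in atoms:
            pname = f" {name:<3}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:>5} {pname}{'':1}{resname:>3} {chain}"
                f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {elem:>2}")
            serial += 1
    return lines


def fragment_as_pdb_residues(frag: Fragment, start_resnum=1,
                             heavy_only=True, drop=()):
    """Convert a Fragment to the residue tuples pdb_lines expects."""
    residues = []
    n_res = frag.n_residues
    for r in range(n_res):
        if n_res == 2:
            resname = frag.label[:3] if r == 0 else frag.label[3:]
        else:
            resname = frag.label
        atoms = []
        for name, elem, xyz, ri in zip(frag.atom_names, frag.elements,
                                       frag.coords, frag.res_indices):
            if ri != r:
                continue
            if heavy_only and elem == "H":
                continue
            if (name, r) in drop or name in drop:
                continue
            atoms.append((name, elem, tuple(xyz)))
        residues.append((resname, start_resnum + r, atoms))
    return residues


@pytest.fixture(scope="session")
def ala_fragment():
    return make_fragment("ALA")


@pytest.fixture(scope="session")
def pro_fragment():
    return make_fragment("PRO")


@pytest.fixture(scope="session")
def met_ensemble():
    return generate_class_ensemble(ConformerSpec("MET", 40, seed=7))


@pytest.fixture(scope="session")
def synthetic_store(tmp_path_factory):
    """Small multi-class store with raw coordinates + all fast features."""
    from flexfrag.generator import generate_dataset
    from flexfrag import workflows

    path = tmp_path_factory.mktemp("store") / "synthetic.h5"
    handle = generate_dataset(["ALA", "GLY", "SER"], 30, seed=11, path=path)
    workflows.featurize_store(handle, reps=("points", "voxel", "hilbert"),
                              seed=0)
    yield handle
    handle.close()
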