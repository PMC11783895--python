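"""Synthetic conformer ensembles by dihedral sampling.

Every in-class difference between real fragments of one class maps to the
same covalent graph with rotations about dihedral angles; the generator
emulates exactly that heterogeneity: bond lengths and angles stay at the
template's ideal values, and only the named rotatable torsions vary.
Backbone angles are drawn from broad but plausible ranges (to limit steric
clashes) while side-chain torsions are uniform; a ``k_modes`` mode draws
torsions from a few tight angular modes instead, producing clusterable
ensembles for testing blocked splits.  Clashing conformers (any nonbonded
pair closer than 1 A) are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import chemistry
from .fragments import Fragment
from .store import DatasetHandle

__all__ = [
    "ConformerSpec",
    "build_conformer",
    "generate_class_ensemble",
    "generate_dataset",
    "topology_dict",
]

#: nonbonded clash threshold (A) triggering a resample
CLASH_DISTANCE = 1.0
MAX_RETRIES = 100

#: sampling ranges (deg) for backbone-like torsions; side-chain torsions
#: ("chi*") and amine rotations are uniform over the full circle
BACKBONE_RANGES = {
    "psi": (-75.0, 170.0),
    "psi1": (-75.0, 170.0),
    "psi2": (-75.0, 170.0),
    "phi2": (-160.0, -45.0),
}
#: torsions held fixed during sampling (trans peptide bond)
FIXED_TORSIONS = ("omega",)


@dataclass(frozen=True)
class ConformerSpec:
    """Recipe for one class ensemble."""

    code: str
    n_conformers: int
    seed: int = 0
    mode: str = "uniform_dihedrals"  # or "k_modes"
    n_modes: int = 2
    spread: float = 5.0  # stddev (deg) around each mode center
    mode_centers: dict | None = None  # optional {torsion: [centers per mode]}

    def __post_init__(self):
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.mode not in ("uniform_dihedrals", "k_modes"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


def _template_for(code: str) -> chemistry.ResidueTemplate:
    code = code.upper().strip()
    if len(code) == 6:
        return chemistry.dipeptide_template(code[:3], code[3:])
    return chemistry.get_template(code)


def _nonbonded_min(template, coords) -> float:
    bonded = {frozenset(b) for b in template.bonds}
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    for i, j in bonded:
        d[i, j] = d[j, i] = np.inf
    return float(d.min())


def build_conformer(template: chemistry.ResidueTemplate,
                    dihedrals: dict[str, float],
                    source_id: str = "synthetic") -> Fragment:
    """Cartesian fragment with the requested rotatable torsions realized.

    Template bond lengths/angles are exact; raises ValueError if the
    conformation has a nonbonded contact below 1 A.
    """
    unknown = set(dihedrals) - set(template.rotatable_dihedrals)
    if unknown:
        raise KeyError(f"{template.code} has no torsions {sorted(unknown)}")
    coords = chemistry.build_coordinates(template, dihedrals)
    if _nonbonded_min(template, coords) < CLASH_DISTANCE:
        raise ValueError(f"steric clash in {template.code} conformer")
    return Fragment(
        label=template.code,
        atom_names=[a.name for a in template.atoms],
        elements=[a.element for a in template.atoms],
        coords=coords,
        source_id=source_id,
        n_residues=template.n_residues,
        res_indices=np.array([a.res_index for a in template.atoms]),
    )


def _mode_centers(template, spec: ConformerSpec, mode_id: int) -> dict:
    """Clash-free torsion centers for one mode, deterministic given seed."""
    names = [n for n in template.rotatable_dihedrals
             if n not in FIXED_TORSIONS]
    if spec.mode_centers:
        return {n: spec.mode_centers[n][mode_id] for n in names
                if n in spec.mode_centers}
    for attempt in range(MAX_RETRIES):
        crng = np.random.default_rng([spec.seed, mode_id, attempt])
        centers = {n: float(crng.uniform(-180.0, 180.0)) for n in names}
        try:
            build_conformer(template, centers)
            return centers
        except ValueError:
            continue
    raise RuntimeError(
        f"no clash-free mode center found for {template.code}")


def _sample_torsions(template, spec: ConformerSpec, rng, centers):
    out = {}
    for name in template.rotatable_dihedrals:
        if name in FIXED_TORSIONS:
            continue
        if spec.mode == "k_modes":
            out[name] = rng.normal(centers[name], spec.spread)
        elif name in BACKBONE_RANGES:
            lo, hi = BACKBONE_RANGES[name]
            out[name] = rng.uniform(lo, hi)
        else:
            out[name] = rng.uniform(-180.0, 180.0)
    return out


def generate_class_ensemble(spec: ConformerSpec) -> list[Fragment]:
    """``n_conformers`` fragments of one class; deterministic given seed."""
    template = _template_for(spec.code)
    rng = np.random.default_rng(spec.seed)
    centers = ([_mode_centers(template, spec, m) for m in range(spec.n_modes)]
               if spec.mode == "k_modes" else [None])
    fragments = []
    for i in range(spec.n_conformers):
        mode_id = i % spec.n_modes if spec.mode == "k_modes" else 0
        for attempt in range(MAX_RETRIES):
            torsions = _sample_torsions(template, spec, rng,
                                        centers[mode_id % len(centers)])
            try:
                frag = build_conformer(template, torsions,
                                       source_id=f"synthetic:{spec.code}:{i}")
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"could not build a clash-free {spec.code} conformer "
                f"after {MAX_RETRIES} attempts")
        fragments.append(frag)
    return fragments


def topology_dict(template: chemistry.ResidueTemplate) -> dict:
    """JSON-serializable topology record stored next to the features."""
    return {
        "code": template.code,
        "atoms": [a.name for a in template.atoms],
        "elements": [a.element for a in template.atoms],
        "res_indices": [a.res_index for a in template.atoms],
        "bonds": [list(b) for b in template.bonds],
    }


def generate_dataset(classes, n_per_class: int, seed: int = 0,
                     path="synthetic.h5", mode: str = "uniform_dihedrals",
                     n_modes: int = 2, spread: float = 5.0) -> DatasetHandle:
    """Balanced raw-coordinate store for the requested classes.

    Writes a heterogeneous ``coord`` collection (full-atom coordinates),
    the shared label table and per-class topologies; the returned handle is
    open for reading and ready for featurization/splitting/training.
    """
    classes = [c.upper().strip() for c in classes]
    if not classes:
        raise ValueError("no classes requested")
    handle = DatasetHandle(path, "w")
    for k, code in enumerate(classes):
        spec = ConformerSpec(code, n_per_class, seed=seed + 7919 * k,
                             mode=mode, n_modes=n_modes, spread=spread)
        fragments = generate_class_ensemble(spec)
        handle.write_heterogeneous(
            "coord", [f.coords for f in fragments],
            [code] * len(fragments))
        handle.write_topology(code, topology_dict(_template_for(code)))
    handle.flush()
    return handle
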