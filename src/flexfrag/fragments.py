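"""The Fragment container: one labeled single-residue or dipeptide sample."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from . import chemistry

__all__ = ["Fragment"]

#: hard lower bound on any interatomic separation in a valid fragment (A)
MIN_SEPARATION = 0.5


@dataclass
class Fragment:
    """A chemically completed molecular fragment with Cartesian coordinates.

    ``label`` is a 3-letter residue code or a 6-letter dipeptide code.
    Coordinates are in Angstrom, in whatever frame the source provided
    (fragments are deliberately not pre-aligned).
    """

    label: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    source_id: str = ""
    n_residues: int = 1
    res_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if self.res_indices is None:
            self.res_indices = np.zeros(len(self.atom_names), dtype=np.int8)
        else:
            self.res_indices = np.asarray(self.res_indices, dtype=np.int8)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask]

    def validate(self) -> None:
        """Raise ValueError if the fragment violates its invariants."""
        expected = chemistry.atom_count(self.label)
        if self.n_atoms != expected:
            raise ValueError(
                f"{self.label}: {self.n_atoms} atoms, template has {expected}")
        if self.coords.shape != (self.n_atoms, 3):
            raise ValueError("coords shape does not match atom list")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.n_atoms > 1 and pdist(self.coords).min() < MIN_SEPARATION:
            raise ValueError(
                f"atoms closer than {MIN_SEPARATION} A in {self.label}")
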