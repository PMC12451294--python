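"""Core domain types: pharmacophores, pockets, ligand records.

Coordinates are in Angstrom throughout, in the right-handed frame of the
source PDB/SDF file.  No recentering happens at I/O time; translation into
a model frame is an explicit graph-construction step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class FeatureType(enum.IntEnum):
    """The six pharmacophore feature classes.

    The integer value is the canonical one-hot index used in every
    serialization and in the diffusion model's 6-dim feature vector.
    """

    HYDROGEN_ACCEPTOR = 0
    HYDROGEN_DONOR = 1
    HYDROPHOBIC = 2
    AROMATIC = 3
    NEGATIVE_ION = 4
    POSITIVE_ION = 5

    @property
    def label(self) -> str:
        """Pharmit-dialect spelling of the feature name."""
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "FeatureType":
        try:
            return _LABEL_TO_TYPE[label]
        except KeyError:
            raise ValueError(
                f"unknown feature name {label!r}; valid names are "
                + ", ".join(_LABELS.values())
            ) from None


_LABELS = {
    FeatureType.HYDROGEN_ACCEPTOR: "HydrogenAcceptor",
    FeatureType.HYDROGEN_DONOR: "HydrogenDonor",
    FeatureType.HYDROPHOBIC: "Hydrophobic",
    FeatureType.AROMATIC: "Aromatic",
    FeatureType.NEGATIVE_ION: "NegativeIon",
    FeatureType.POSITIVE_ION: "PositiveIon",
}
_LABEL_TO_TYPE = {v: k for k, v in _LABELS.items()}

N_FEATURE_TYPES = 6

#: Fixed protein atom-type vocabulary; index 9 is the catch-all.
ATOM_TYPES = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "other")
N_ATOM_TYPES = len(ATOM_TYPES)
_ATOM_TYPE_INDEX = {sym: i for i, sym in enumerate(ATOM_TYPES)}


def atom_type_index(element: str) -> int:
    """Map an element symbol to its one-hot index (unknown -> 'other')."""
    return _ATOM_TYPE_INDEX.get(element.capitalize(), N_ATOM_TYPES - 1)


@dataclass(frozen=True)
class PharmacophoreCenter:
    """One typed interaction point: 3D position plus feature class."""

    position: np.ndarray  # shape (3,), Angstrom
    ftype: FeatureType
    radius: float = 1.0  # query tolerance sphere, Angstrom

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("center position must be a finite 3-vector")
        if not self.radius > 0:
            raise ValueError("center radius must be > 0")
        object.__setattr__(self, "position", pos)

    def isclose(self, other: "PharmacophoreCenter", atol: float = 1e-6) -> bool:
        return (
            self.ftype == other.ftype
            and abs(self.radius - other.radius) <= atol
            and bool(np.allclose(self.position, other.position, atol=atol))
        )


@dataclass
class Pharmacophore:
    """An ordered set of pharmacophore centers."""

    centers: list[PharmacophoreCenter]

    def __post_init__(self):
        if len(self.centers) < 1:
            raise ValueError("a pharmacophore needs at least one center")

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of center coordinates."""
        return np.array([c.position for c in self.centers], dtype=float)

    @property
    def types(self) -> list[FeatureType]:
        return [c.ftype for c in self.centers]

    def one_hot(self) -> np.ndarray:
        """(N, 6) one-hot feature matrix in canonical type order."""
        out = np.zeros((len(self.centers), N_FEATURE_TYPES))
        for i, c in enumerate(self.centers):
            out[i, int(c.ftype)] = 1.0
        return out

    def isclose(self, other: "Pharmacophore", atol: float = 1e-6) -> bool:
        return len(self) == len(other) and all(
            a.isclose(b, atol) for a, b in zip(self.centers, other.centers)
        )


@dataclass(frozen=True)
class PocketAtom:
    """A protein heavy (or hydrogen) atom inside the binding pocket."""

    element: str
    position: np.ndarray  # (3,), Angstrom
    residue: str  # e.g. "A:42:ASP"
    atom_name: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def type_index(self) -> int:
        return atom_type_index(self.element)


@dataclass
class Pocket:
    """A binding pocket: atoms plus (optionally cached) protein-side features."""

    atoms: list[PocketAtom]
    complementary_features: Optional[list[tuple[FeatureType, np.ndarray]]] = None

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("empty pocket")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def type_indices(self) -> np.ndarray:
        return np.array([a.type_index for a in self.atoms], dtype=int)

    def atom_one_hot(self) -> np.ndarray:
        out = np.zeros((len(self.atoms), N_ATOM_TYPES))
        out[np.arange(len(self.atoms)), self.type_indices] = 1.0
        return out

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class Conformer:
    """One 3D pose of a molecule.

    ``mol`` optionally caches an RDKit molecule carrying this geometry; it is
    built on demand by the featurizer when absent.
    """

    coords: np.ndarray  # (n_atoms, 3)
    elements: list[str]
    formal_charges: list[int]
    bonds: list[tuple[int, int, int]]  # (i, j, order); order 12 = aromatic
    mol: object = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if len(self.elements) != n or len(self.formal_charges) != n:
            raise ValueError("conformer field lengths disagree")


@dataclass
class LigandRecord:
    """A molecule with one or more conformers, optionally labelled active."""

    mol_id: str
    conformers: list[Conformer]
    active_label: Optional[bool] = None

    def __post_init__(self):
        if not self.conformers:
            raise ValueError(f"ligand {self.mol_id!r} has no conformers")
        n = self.conformers[0].coords.shape[0]
        for c in self.conformers:
            if c.coords.shape[0] != n:
                raise ValueError(
                    f"ligand {self.mol_id!r}: conformers disagree on atom count"
                )
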