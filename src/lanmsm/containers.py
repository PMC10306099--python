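"""Core in-memory containers shared across the pipeline.

All coordinates are stored in Angstrom throughout the package (PDB native
units); feature values are Angstrom for distances and unitless fractions for
helicity. Residue numbering follows the input file's own residue sequence
numbers (1-based, as in "Thr11") and is never renumbered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "FeatureMatrix",
    "RingDefinition",
    "DEFAULT_RING_CUTOFFS",
]

#: Shipped ring-closure cutoffs in Angstrom per atom-selection mode:
#: the Cbeta-Sgamma reactive distance uses 7.5 A; the closest-heavy-atom
#: alternative uses 4.5 A.
DEFAULT_RING_CUTOFFS = {"cb_sg": 7.5, "heavy_min": 4.5}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int  # 1-based residue sequence number


class Topology:
    """Ordered residues and atoms of a peptide.

    Parameters
    ----------
    residues : sequence of (index, name)
        1-based residue sequence numbers (strictly increasing) with their
        3-letter residue codes.
    atoms : sequence of Atom
        Atoms in file order; each must reference an existing residue and
        carry a non-empty element symbol.
    """

    def __init__(self, residues, atoms):
        residues = [(int(i), str(n)) for i, n in residues]
        indices = [i for i, _ in residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be strictly increasing")
        known = set(indices)
        for atom in atoms:
            if atom.residue_index not in known:
                raise ValueError(
                    f"atom {atom.name!r} (serial {atom.serial}) references "
                    f"unknown residue {atom.residue_index}"
                )
            if not atom.element:
                raise ValueError(
                    f"atom {atom.name!r} (serial {atom.serial}) has empty element"
                )
        self.residues = residues
        self.atoms = list(atoms)
        self._by_residue: dict[int, dict[str, int]] = {i: {} for i in indices}
        for k, atom in enumerate(self.atoms):
            self._by_residue[atom.residue_index].setdefault(atom.name, k)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def residue_indices(self) -> list[int]:
        return [i for i, _ in self.residues]

    def residue_name(self, residue_index: int) -> str:
        for i, name in self.residues:
            if i == residue_index:
                return name
        raise KeyError(f"no residue {residue_index}")

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return atom_name in self._by_residue.get(residue_index, {})

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Flat atom index of *atom_name* in residue *residue_index*."""
        try:
            return self._by_residue[residue_index][atom_name]
        except KeyError:
            raise KeyError(
                f"residue {residue_index} has no atom named {atom_name!r}"
            ) from None

    def residue_atom_indices(self, residue_index: int, heavy_only: bool = False):
        out = [
            k
            for k, a in enumerate(self.atoms)
            if a.residue_index == residue_index
            and (not heavy_only or a.element.upper() != "H")
        ]
        return out

    def __eq__(self, other):
        return (
            isinstance(other, Topology)
            and self.residues == other.residues
            and self.atoms == other.atoms
        )


class Trajectory:
    """Frames of 3-D coordinates (Angstrom) bound to a Topology."""

    def __init__(self, topology: Topology, coordinates, frame_spacing: float = 1.0,
                 source_id: str = ""):
        coordinates = np.asarray(coordinates, dtype=np.float64)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if coordinates.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if coordinates.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coordinates.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if not np.isfinite(coordinates).all():
            raise ValueError("non-finite coordinates")
        self.topology = topology
        self.coordinates = coordinates
        self.frame_spacing = float(frame_spacing)
        self.source_id = source_id

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, index: int) -> "Trajectory":
        return Trajectory(self.topology, self.coordinates[index:index + 1],
                          self.frame_spacing, self.source_id)


class FeatureMatrix:
    """frames x named-features array tagged by source trajectory."""

    def __init__(self, values, feature_names, source_id: str = ""):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        feature_names = [str(n) for n in feature_names]
        if len(feature_names) != values.shape[1]:
            raise ValueError("feature_names length must match value columns")
        if len(set(feature_names)) != len(feature_names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(values).all():
            raise ValueError("non-finite feature values")
        self.values = values
        self.feature_names = feature_names
        self.source_id = source_id

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None
        return self.values[:, j]

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if other.n_frames != self.n_frames:
            raise ValueError("frame counts differ")
        return FeatureMatrix(
            np.hstack([self.values, other.values]),
            self.feature_names + other.feature_names,
            self.source_id,
        )


@dataclass
class RingDefinition:
    """A candidate thioether ring: a Thr/Ser-like and a Cys residue pair.

    ``mode`` selects the reactive-distance definition: ``cb_sg`` is the
    Cbeta(Thr)-Sgamma(Cys) distance (default cutoff 7.5 A), ``heavy_min``
    the minimum over all heavy-atom pairs (default cutoff 4.5 A).
    """

    thr_residue: int
    cys_residue: int
    mode: str = "cb_sg"
    cutoff: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.mode not in DEFAULT_RING_CUTOFFS:
            raise ValueError(f"unknown ring mode {self.mode!r}")
        if self.thr_residue == self.cys_residue:
            raise ValueError("ring residues must be distinct")
        if self.cutoff is None:
            self.cutoff = DEFAULT_RING_CUTOFFS[self.mode]
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.label:
            self.label = f"r{self.thr_residue}-r{self.cys_residue}"

    def validate_against(self, topology: Topology) -> None:
        for r in (self.thr_residue, self.cys_residue):
            if r not in topology.residue_indices:
                raise ValueError(f"ring residue {r} not in topology")
        if self.mode == "cb_sg":
            if not topology.has_atom(self.thr_residue, "CB"):
                raise ValueError(
                    f"residue {self.thr_residue} lacks atom 'CB' required by cb_sg mode"
                )
            if not topology.has_atom(self.cys_residue, "SG"):
                raise ValueError(
                    f"residue {self.cys_residue} lacks atom 'SG' required by cb_sg mode"
                )
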