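"""Domain types: atoms, structures, trajectories, selections and node maps.

Coordinates are in Angstrom throughout.  Frames are 0-indexed internally
and 1-indexed wherever they are written to reports (matching the MODEL
numbering of multi-model PDB files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyStructureError, SelectionError, TopologyError

# residue names treated as standard amino acids (nodes anchored at CA)
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER
    THR TRP TYR VAL MSE SEC PYL""".split()
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure.

    ``het`` flags HETATM provenance (ligands, ions, waters).
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    b_factor: float = 0.0
    element: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")
        object.__setattr__(self, "coords", coords)
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for atom serial {self.serial}")


class Structure:
    """An ordered collection of atoms with residue/ligand bookkeeping."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = list(atoms)
        if not atoms:
            raise EmptyStructureError("structure contains no atoms")
        seen: set[tuple[str, int, str, str]] = set()
        for a in atoms:
            key = (a.chain_id, a.residue_seq, a.residue_name, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} within structure")
            seen.add(key)
        self.atoms: list[AtomRecord] = atoms

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def b_factors(self) -> np.ndarray:
        return np.array([a.b_factor for a in self.atoms], dtype=float)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[int]]]:
        """Yield ((chain_id, residue_seq, residue_name), atom indices), in
        first-occurrence order."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_seq, a.residue_name)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        for key in order:
            yield key, groups[key]

    @property
    def ligands(self) -> list[tuple[str, list[int]]]:
        """HETATM residues as (residue_name, atom index list)."""
        out = []
        for (chain, seq, resname), idx in self.residues():
            if all(self.atoms[i].het for i in idx):
                out.append((resname, idx))
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.serial, a.name, a.residue_name, a.chain_id, a.residue_seq,
                       coords[i], a.b_factor, a.element, a.het)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms)


class Trajectory:
    """F frames of N atoms sharing one topology.

    Invariants: F >= 2, every frame matches the topology atom count, all
    coordinates finite.
    """

    def __init__(self, frames: np.ndarray, topology: Structure,
                 frame_interval: float = 1.0):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, N, 3), got {frames.shape}")
        if frames.shape[0] < 2:
            raise TopologyError("a trajectory needs at least 2 frames")
        if frames.shape[1] != len(topology):
            raise TopologyError(
                f"frames have {frames.shape[1]} atoms but topology has {len(topology)}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError("non-finite coordinates in trajectory")
        self.frames = frames
        self.topology = topology
        self.frame_interval = float(frame_interval)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])

    def with_frames(self, frames: np.ndarray) -> "Trajectory":
        return Trajectory(frames, self.topology, self.frame_interval)


@dataclass(frozen=True)
class Selection:
    """An ordered subset of topology atoms."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SelectionError("selection indices must be strictly increasing")
        if idx and idx[0] < 0:
            raise SelectionError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def validate(self, n_atoms: int) -> None:
        if self.indices and self.indices[-1] >= n_atoms:
            raise SelectionError(
                f"selection index {self.indices[-1]} out of range for {n_atoms} atoms"
            )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def select_atoms(structure: Structure, names: Sequence[str] = ("CA",),
                 include_het: bool = False, label: str = "") -> Selection:
    """Select atoms by name; default picks the Cα trace."""
    wanted = set(names)
    idx = [
        i for i, a in enumerate(structure.atoms)
        if a.name in wanted and (include_het or not a.het)
    ]
    if not idx:
        raise SelectionError(f"no atoms named {sorted(wanted)} in structure")
    return Selection(tuple(idx), label or "+".join(sorted(wanted)))


@dataclass
class NodeMap:
    """Network nodes anchored at topology atoms.

    One node per amino-acid residue (anchored at Cα); a ligand may
    contribute several nodes, one per configured anchor atom.
    """

    labels: list[str]
    anchor_indices: np.ndarray
    chain_ids: list[str] = field(default_factory=list)
    residue_seqs: list[int] = field(default_factory=list)
    is_ligand: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    residue_atoms: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.anchor_indices = np.asarray(self.anchor_indices, dtype=int)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")
        if len(self.labels) != len(self.anchor_indices):
            raise ValueError("labels and anchors length mismatch")
        if len(self.is_ligand) == 0:
            self.is_ligand = np.zeros(len(self.labels), dtype=bool)
        if not self.residue_atoms:
            self.residue_atoms = [(int(i),) for i in self.anchor_indices]

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SelectionError(f"unknown node label {label!r}") from None

    def anchor_selection(self) -> Selection:
        order = np.argsort(self.anchor_indices, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            raise SelectionError("node anchors are not in increasing atom order")
        return Selection(tuple(int(i) for i in self.anchor_indices), "node-anchors")


def identity_node_map(n: int, prefix: str = "N") -> NodeMap:
    """Node map for a bare N-point topology (one node per atom)."""
    return NodeMap(
        labels=[f"{prefix}{i + 1}" for i in range(n)],
        anchor_indices=np.arange(n),
        chain_ids=["A"] * n,
        residue_seqs=list(range(1, n + 1)),
    )
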