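"""Reading and writing structures/trajectories as (multi-model) PDB.

A fixed-column PDB v3.3 reader/writer is implemented here rather than
delegated to a general-purpose parser: the contracts below require strict
line-level error reporting (truncated records must fail loudly, naming the
line) and bit-exact round-trips through the canonical interchange format,
which permissive readers do not guarantee.

Handling rules: altloc '' or 'A' kept, others dropped; insertion-coded
residues dropped (single-conformer topology).  HETATM atoms are retained
and flagged.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyStructureError,
    MissingAnchorError,
    PDBParseError,
    TopologyError,
)
from .model import AMINO_ACIDS, AtomRecord, NodeMap, Structure, Trajectory

# default ligand rule: SAH contributes three nodes (CA, C4', N9)
DEFAULT_LIGAND_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("SAH", ("CA", "C4'", "N9")),
)


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM/HETATM record; None if dropped by altloc/icode rules."""
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
    altloc = line[16]
    if altloc not in (" ", "A"):
        return None
    icode = line[26]
    if icode != " ":
        return None
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed field ({exc})") from None
    bfac = 0.0
    if len(line) >= 66 and line[60:66].strip():
        try:
            bfac = float(line[60:66])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed B-factor ({exc})") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = "".join(c for c in name if c.isalpha())[:1]
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=resname,
        chain_id=chain,
        residue_seq=resseq,
        coords=np.array([x, y, z]),
        b_factor=max(bfac, 0.0),
        element=element,
        het=line.startswith("HETATM"),
    )


def _atom_key(a: AtomRecord) -> tuple[str, int, str, str]:
    return (a.chain_id, a.residue_seq, a.residue_name, a.name)


def read_structure(path: str | os.PathLike, dialect: str = "pdb") -> Structure:
    """Read a single-model structure from a PDB file.

    For multi-model files the first model is returned.
    """
    if dialect.lower() != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    atoms.append(atom)
            elif rec.startswith(("ENDMDL", "END ")) or line.strip() == "END":
                if atoms:
                    break
    if not atoms:
        raise EmptyStructureError(f"no atoms found in {path}")
    return Structure(atoms)


def read_trajectory(path: str | os.PathLike, frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a Trajectory (topology = first model)."""
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                models.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom is None:
                    continue
                if current is None:
                    current = []  # tolerate files without MODEL for frame 1
                current.append(atom)
    if current:
        models.append(current)
    if len(models) < 2:
        raise TopologyError(
            f"{path}: need at least 2 MODEL blocks, found {len(models)}"
        )
    ref_keys = [_atom_key(a) for a in models[0]]
    for m, atoms in enumerate(models[1:], start=2):
        if [_atom_key(a) for a in atoms] != ref_keys:
            raise TopologyError(
                f"{path}: model {m} atom list differs from model 1"
            )
    topology = Structure(models[0])
    frames = np.array([[a.coords for a in atoms] for atoms in models])
    return Trajectory(frames, topology, frame_interval)


def _format_atom(a: AtomRecord, serial: int, coords: np.ndarray) -> str:
    rec = "HETATM" if a.het else "ATOM  "
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{rec}{serial:>5d} {name:<4s} {a.residue_name:>3s} {a.chain_id}"
        f"{a.residue_seq:>4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{a.b_factor:6.2f}          {a.element:>2s}\n"
    )


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            fh.write(_format_atom(a, i, a.coords))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a Trajectory as a multi-model PDB (one MODEL per frame)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL {f + 1:>8d}\n")
            for i, a in enumerate(traj.topology.atoms, start=1):
                fh.write(_format_atom(a, i, traj.frames[f, i - 1]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def build_node_map(
    structure: Structure,
    ligand_rules: Iterable[tuple[str, Sequence[str]]] = DEFAULT_LIGAND_RULES,
) -> NodeMap:
    """One node per amino acid at its Cα; ligand nodes per anchor rule.

    Residue nodes are ordered by (chain, residue_seq); ligand nodes are
    appended.  HETATM residues not covered by a rule (ions, waters) are
    excluded.
    """
    rules = {resname: tuple(anchors) for resname, anchors in ligand_rules}
    residue_entries = []  # (chain, seq, label, anchor, atom_idx_tuple)
    ligand_entries = []
    missing: list[str] = []
    for (chain, seq, resname), idx in structure.residues():
        het = all(structure.atoms[i].het for i in idx)
        if not het and resname in AMINO_ACIDS:
            by_name = {structure.atoms[i].name: i for i in idx}
            if "CA" not in by_name:
                missing.append(f"{chain}:{resname}{seq}")
                continue
            heavy = tuple(
                i for i in idx if structure.atoms[i].element.upper() != "H"
            )
            residue_entries.append(
                (chain, seq, f"{chain}:{resname}{seq}", by_name["CA"], heavy)
            )
        elif resname in rules:
            by_name = {structure.atoms[i].name: i for i in idx}
            for anchor in rules[resname]:
                if anchor not in by_name:
                    raise MissingAnchorError(
                        f"ligand {chain}:{resname}{seq} has no atom {anchor!r}"
                    )
                ligand_entries.append(
                    (chain, seq, f"{chain}:{resname}{seq}:{anchor}",
                     by_name[anchor], (by_name[anchor],))
                )
    if missing:
        raise MissingAnchorError(
            "residues without a C-alpha anchor: " + ", ".join(missing)
        )
    residue_entries.sort(key=lambda e: (e[0], e[1]))
    entries = residue_entries + ligand_entries
    if not entries:
        raise MissingAnchorError("structure yields no network nodes")
    n_res = len(residue_entries)
    return NodeMap(
        labels=[e[2] for e in entries],
        anchor_indices=np.array([e[3] for e in entries], dtype=int),
        chain_ids=[e[0] for e in entries],
        residue_seqs=[e[1] for e in entries],
        is_ligand=np.array([i >= n_res for i in range(len(entries))], dtype=bool),
        residue_atoms=[e[4] for e in entries],
    )
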