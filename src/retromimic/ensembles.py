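"""Conformer ensembles: containers, multi-model PDB I/O, frame selection.

An ensemble is an ordered set of Cartesian snapshots of one molecule, the
in-memory analogue of a simulation trajectory thinned for analysis. Atom
metadata (names, elements, masses, residue assignment) is shared across
frames; coordinates are an ``(n_frames, n_atoms, 3)`` array in Å.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from .errors import InputError
from .peptides import ONE_LETTER, THREE_LETTER


@dataclass(frozen=True)
class Atom:
    """Per-atom metadata shared by every frame of an ensemble."""

    atom_name: str
    element: str
    mass: float  # Da
    residue_index: int  # 1-based
    residue_code: str  # one-letter
    chirality: str | None = None  # 'L' | 'D' | 'achiral' | None (unknown)


@dataclass
class ConformerEnsemble:
    """Ordered coordinate snapshots of one molecule.

    Invariants enforced at construction: every frame has the same atom
    count and ordering, residue indices are non-decreasing along the atom
    list, and all masses are strictly positive.
    """

    atoms: tuple[Atom, ...]
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InputError(
                f"frames must have shape (n_frames, n_atoms, 3), "
                f"got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise InputError("ensemble must contain at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise InputError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"atom metadata length {len(self.atoms)}"
            )
        res_idx = [a.residue_index for a in self.atoms]
        if any(b < a for a, b in zip(res_idx, res_idx[1:])):
            raise InputError("residue_index must be non-decreasing along atoms")
        if any(a.mass <= 0 for a in self.atoms):
            raise InputError("atomic masses must be strictly positive")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise InputError("frame_times length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def residue_codes(self) -> tuple[str, ...]:
        """One-letter codes in residue order."""
        seen: dict[int, str] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, a.residue_code)
        return tuple(seen[k] for k in sorted(seen))

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return i
        raise InputError(
            f"no atom {atom_name!r} in residue {residue_index}"
        )

    def subset(self, frame_indices: np.ndarray) -> "ConformerEnsemble":
        idx = np.asarray(frame_indices, dtype=int)
        times = None if self.frame_times is None else self.frame_times[idx]
        return ConformerEnsemble(self.atoms, self.frames[idx], times)


def _model_atom_counts(text: str) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (whole file = one model
    if no MODEL records are present)."""
    counts: list[int] = []
    in_model = False
    current = 0
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        return [current] if current else []
    if in_model:  # unterminated final MODEL
        counts.append(current)
    return counts


def read_multimodel_pdb(path: str | Path) -> ConformerEnsemble:
    """Read a multi-model PDB into an ensemble (one frame per MODEL).

    Masses come from an element lookup; residue codes from the standard
    three-letter names. A file without MODEL records yields a one-frame
    ensemble.

    Raises
    ------
    InputError
        If models disagree in atom count (the message names the first
        offending model) or no coordinates are present.
    """
    text = Path(path).read_text()
    counts = _model_atom_counts(text)
    if not counts:
        raise InputError(f"no coordinates found in {path}")
    for model_no, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise InputError(
                f"inconsistent atom counts in {path}: model {model_no} has "
                f"{c} atoms, model 1 has {counts[0]}"
            )
    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    atoms = []
    for i in range(stack.array_length()):
        elem = str(stack.element[i]).capitalize()
        res3 = str(stack.res_name[i])
        atoms.append(
            Atom(
                atom_name=str(stack.atom_name[i]),
                element=elem,
                mass=float(struc_info.mass(elem)),
                residue_index=int(stack.res_id[i]),
                residue_code=ONE_LETTER.get(res3, "X"),
            )
        )
    for a in atoms:
        if a.residue_code == "X":
            raise InputError(
                f"non-canonical residue name in {path} at residue "
                f"{a.residue_index}"
            )
    return ConformerEnsemble(tuple(atoms), np.asarray(stack.coord, dtype=float))


def write_multimodel_pdb(ens: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame).

    Coordinates round-trip to the PDB fixed-format precision (3 decimals,
    i.e. 0.001 Å).
    """
    n = ens.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.zeros((n, 3))
    arr.atom_name = np.array([a.atom_name for a in ens.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in ens.atoms], dtype="U2")
    arr.res_id = np.array([a.residue_index for a in ens.atoms])
    arr.res_name = np.array(
        [THREE_LETTER.get(a.residue_code, "UNK") for a in ens.atoms], dtype="U5"
    )
    arr.chain_id = np.array(["A"] * n, dtype="U4")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * ens.n_frames)
    stack.coord = np.asarray(ens.frames, dtype=float)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def select_equilibrated_frames(
    ens: ConformerEnsemble,
    equilibrated_fraction: float = 2 / 3,
    n_frames: int = 1000,
) -> ConformerEnsemble:
    """Keep the equilibrated tail and thin it to equally spaced frames.

    The final ``equilibrated_fraction`` of frames is treated as
    equilibrated (default 2/3, i.e. the last 100 ns of a 150 ns run);
    ``n_frames`` equally spaced frames are then drawn from that tail,
    always including its first and last frame. The selected indices are
    ``round(i * (M-1) / (n-1))`` over the tail of length ``M``.
    """
    if not 0 < equilibrated_fraction <= 1:
        raise InputError("equilibrated_fraction must be in (0, 1]")
    total = ens.n_frames
    tail_len = int(round(total * equilibrated_fraction))
    tail_len = max(1, min(total, tail_len))
    start = total - tail_len
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    if n_frames > tail_len:
        raise InputError(
            f"requested {n_frames} frames but only {tail_len} available "
            f"in the equilibrated tail"
        )
    if n_frames == 1:
        rel = np.array([tail_len - 1])
    else:
        rel = np.round(
            np.arange(n_frames) * (tail_len - 1) / (n_frames - 1)
        ).astype(int)
    return ens.subset(start + rel)
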