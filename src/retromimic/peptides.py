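"""Peptide sequences with per-residue chirality and the retro-D transformation.

A retro-D (retro-inverso / retro-enantio) peptide is obtained from a parent
L-peptide by reversing the sequence and inverting the Cα configuration of
every residue. Because the side chain of residue ``i`` in the parent then
sits on residue ``N+1-i`` of the retro-D version, the two molecules can
present near-identical side-chain topology while the backbone amide
direction is reversed.

Case encodes chirality in text form: uppercase letters are L-residues,
lowercase are D-residues. Glycine is achiral and always serialized
uppercase. That convention is a serialization only; the per-residue
``chirality`` annotation is the internal truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

from .errors import InputError

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

L = "L"
D = "D"
ACHIRAL = "achiral"


@dataclass(frozen=True)
class Residue:
    """One residue: canonical one-letter code plus Cα chirality."""

    code: str
    chirality: str

    def __post_init__(self) -> None:
        if self.code not in CANONICAL_AA:
            raise InputError(f"not a canonical amino acid: {self.code!r}")
        if self.code == "G":
            if self.chirality != ACHIRAL:
                raise InputError("glycine is achiral")
        elif self.chirality not in (L, D):
            raise InputError(
                f"chirality must be 'L' or 'D' for {self.code}, "
                f"got {self.chirality!r}"
            )

    def inverted(self) -> "Residue":
        """The enantiomeric residue (glycine is its own mirror image)."""
        if self.chirality == ACHIRAL:
            return self
        return Residue(self.code, D if self.chirality == L else L)


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered peptide sequence with termini chemistry.

    All four peptides this package was built around are synthesized as
    C-terminal amides with a free N-terminal amine, so those are the
    defaults.
    """

    residues: tuple[Residue, ...]
    n_terminus: str = "free-amine"
    c_terminus: str = "amide"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InputError("a peptide needs at least one residue")
        if self.n_terminus not in ("free-amine", "acetyl"):
            raise InputError(f"unknown N-terminus {self.n_terminus!r}")
        if self.c_terminus not in ("amide", "acid"):
            raise InputError(f"unknown C-terminus {self.c_terminus!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __str__(self) -> str:
        return to_string(self)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.residues)


def parse_sequence(text: str) -> PeptideSequence:
    """Parse a one-letter sequence where case encodes chirality.

    Uppercase letters become L-residues, lowercase become D-residues;
    glycine (``G``/``g``) is achiral either way. Whitespace is ignored.

    Raises
    ------
    InputError
        If the string is empty or contains a character that is not a
        canonical amino-acid letter; the message names the 1-based
        position of the first offender.
    """
    stripped = "".join(text.split())
    if not stripped:
        raise InputError("empty sequence")
    residues = []
    for pos, ch in enumerate(stripped, start=1):
        upper = ch.upper()
        if upper not in CANONICAL_AA:
            raise InputError(
                f"invalid amino-acid letter {ch!r} at position {pos}"
            )
        if upper == "G":
            residues.append(Residue("G", ACHIRAL))
        else:
            residues.append(Residue(upper, L if ch.isupper() else D))
    return PeptideSequence(tuple(residues))


def to_string(seq: PeptideSequence) -> str:
    """Serialize with the case convention (uppercase L, lowercase D)."""
    out = []
    for r in seq:
        out.append(r.code.lower() if r.chirality == D else r.code)
    return "".join(out)


def retro_d_transform(seq: PeptideSequence) -> PeptideSequence:
    """Reverse the sequence and invert every residue's chirality.

    Termini chemistry is preserved: the retro-D peptide is synthesized
    with the same free N-terminal amine and C-terminal amide as the
    parent, so the transformation acts on residue order and configuration
    only. The transformation is an involution.
    """
    return replace(
        seq, residues=tuple(r.inverted() for r in reversed(seq.residues))
    )


def is_retro_pair(parent: PeptideSequence, candidate: PeptideSequence) -> bool:
    """True if ``candidate`` is exactly the retro-D version of ``parent``."""
    return retro_d_transform(parent) == candidate


def check_retro_pair(parent: PeptideSequence, candidate: PeptideSequence) -> None:
    """Validate a retro pair, naming the first offending position.

    Positions are reported in the candidate's own 1-based numbering.
    """
    if len(parent) != len(candidate):
        raise InputError(
            f"length mismatch: parent has {len(parent)} residues, "
            f"candidate has {len(candidate)}"
        )
    expected = retro_d_transform(parent)
    for i, (want, got) in enumerate(zip(expected, candidate), start=1):
        if want != got:
            raise InputError(
                f"not a retro-D pair: candidate position {i} is "
                f"{got.code}/{got.chirality}, expected {want.code}/{want.chirality}"
            )


def read_sequences(path: str | Path) -> dict[str, PeptideSequence]:
    """Read sequences from plain text or a FASTA-like file.

    Lines starting with ``>`` open a named record; bare lines are
    anonymous records named ``seq1``, ``seq2``, ... Lowercase letters are
    legal and meaningful (D-residues).
    """
    records: dict[str, list[str]] = {}
    current: str | None = None
    n_anon = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            current = line[1:].strip() or f"seq{len(records) + 1}"
            records.setdefault(current, [])
        elif current is not None:
            records[current].append(line)
        else:
            n_anon += 1
            records[f"seq{n_anon}"] = [line]
            current = None
    if not records:
        raise InputError(f"no sequences found in {path}")
    return {name: parse_sequence("".join(chunks)) for name, chunks in records.items()}
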