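"""RNA sequences and point mutations.

Positions are 1-based throughout the public API, matching the compact
mutation notation used in the human-genetics literature (``C33G`` = the C at
position 33 replaced by a G).  DNA input is accepted everywhere and silently
normalised to RNA (T -> U); mixed case is upper-cased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

RNA_ALPHABET = "ACGU"

_CLEAN = str.maketrans({"t": "U", "T": "U", "a": "A", "c": "C", "g": "G", "u": "U"})

_MUT_RE = re.compile(r"^([ACGTUacgtu])(\d+)([ACGTUacgtu])$")


class SequenceError(ValueError):
    """Raised for malformed sequences or mutations."""


def normalize_residues(raw: str) -> str:
    """Upper-case and convert T->U; reject anything outside {A,C,G,U,T}."""
    cleaned = raw.translate(_CLEAN)
    for offset, ch in enumerate(cleaned):
        if ch not in RNA_ALPHABET:
            raise SequenceError(
                f"illegal residue {raw[offset]!r} at position {offset + 1} "
                "(only A, C, G, U/T are accepted)"
            )
    return cleaned


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with a stable identifier.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Residues over {A,C,G,U}; DNA letters are converted on construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))
        if len(self.residues) == 0:
            raise SequenceError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise SequenceError(
                f"position {position} out of range 1..{len(self.residues)} "
                f"for sequence {self.id!r}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class Mutation:
    """A single-nucleotide substitution in 1-based coordinates."""

    position: int
    wild: str
    variant: str

    def __post_init__(self) -> None:
        wild = normalize_residues(self.wild)
        variant = normalize_residues(self.variant)
        object.__setattr__(self, "wild", wild)
        object.__setattr__(self, "variant", variant)
        if self.position < 1:
            raise SequenceError(f"mutation position must be >= 1, got {self.position}")
        if wild == variant:
            raise SequenceError(
                f"mutation {wild}{self.position}{variant}: wild and variant base are identical"
            )

    @property
    def label(self) -> str:
        return f"{self.wild}{self.position}{self.variant}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    def validate_against(self, seq: RnaSequence) -> None:
        """Check the mutation is applicable to *seq* (position and wild base)."""
        found = seq.residue(self.position)
        if found != self.wild:
            raise SequenceError(
                f"wild-base mismatch for {self.label} on {seq.id!r}: "
                f"expected {self.wild} at position {self.position}, found {found}"
            )


def parse_mutation(text: str, seq: RnaSequence | None = None) -> Mutation:
    """Parse compact mutation notation like ``C33G`` or ``T110G``.

    T is accepted on either side and normalised to U.  If *seq* is given the
    mutation is validated against it (range and wild-base identity).
    """
    m = _MUT_RE.match(text.strip())
    if m is None:
        raise SequenceError(
            f"cannot parse mutation {text!r}: expected <base><position><base>, e.g. C33G"
        )
    mut = Mutation(position=int(m.group(2)), wild=m.group(1), variant=m.group(3))
    if seq is not None:
        mut.validate_against(seq)
    return mut
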