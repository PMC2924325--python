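"""Nested RNA secondary structures and dot-bracket notation."""

from __future__ import annotations

from dataclasses import dataclass


class StructureError(ValueError):
    """Raised for invalid base-pair sets or malformed dot-bracket strings."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs, 1-based, each pair (i, j) with i < j.

    The empty structure (no pairs) is valid and has energy zero by convention.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple(sorted((min(i, j), max(i, j)) for i, j in self.pairs))
        seen: set[int] = set()
        for i, j in pairs:
            if i < 1:
                raise StructureError(f"pair ({i},{j}): positions are 1-based")
            if i == j:
                raise StructureError(f"residue {i} cannot pair with itself")
            for idx in (i, j):
                if idx in seen:
                    raise StructureError(f"residue {idx} appears in more than one pair")
                seen.add(idx)
        for a in range(len(pairs)):
            i, j = pairs[a]
            for b in range(a + 1, len(pairs)):
                k, l = pairs[b]
                if i < k < j < l:
                    raise StructureError(
                        f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknots are not modelled)"
                    )
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def partner_of(self, position: int) -> int | None:
        for i, j in self.pairs:
            if i == position:
                return j
            if j == position:
                return i
        return None

    def to_dotbracket(self, n: int) -> str:
        """Render as a dot-bracket string of length *n*."""
        if self.pairs and max(j for _, j in self.pairs) > n:
            raise StructureError(f"structure has a pair beyond sequence length {n}")
        chars = ["."] * n
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, text: str) -> "SecondaryStructure":
        """Parse a dot-bracket string (round-trips with :meth:`to_dotbracket`)."""
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for pos, ch in enumerate(text.strip(), start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise StructureError(f"unexpected character {ch!r} at position {pos}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(pairs=tuple(pairs))


EMPTY_STRUCTURE = SecondaryStructure(pairs=())
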