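"""Modified-peptide domain model and the lowercase-marked sequence convention.

Redox proteomics tables conventionally print a peptide with modified residues
in lowercase, e.g. ``tcAQDEVLR`` for an N-terminally iTRAQ-labeled peptide
carrying an iodoTMT tag on Cys-2.  This module parses and renders that
convention and holds the monoisotopic mass deltas of the modifications the
workflow uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

N_TERM = "N-term"

IODOTMT = "iodoTMT6plex"
ITRAQ = "iTRAQ8plex"
OXIDATION = "oxidation"
PHOSPHO = "phosphorylation"
NEM = "NEM"

#: modification name -> (target residues, monoisotopic mass delta in Da).
#: ``N`` in a target string stands for the peptide N-terminus.
MOD_MASS_TABLE: dict[str, tuple[str, float]] = {
    NEM: ("C", 124.048),
    IODOTMT: ("C", 329.227),
    ITRAQ: ("NK", 304.205),
    OXIDATION: ("M", 15.995),
    PHOSPHO: ("STY", 79.966),
}

Position = Union[int, str]  # 1-based residue index, or N_TERM


class PeptideParseError(ValueError):
    """A lowercase-marked peptide string violates the marking convention."""


@dataclass(frozen=True)
class Modification:
    position: Position
    name: str

    def __post_init__(self) -> None:
        if self.name not in MOD_MASS_TABLE:
            raise ValueError(f"unknown modification {self.name!r}")

    @property
    def mass_delta(self) -> float:
        return MOD_MASS_TABLE[self.name][1]


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with site-localized modifications.

    Positions are 1-based on the peptide; the string ``"N-term"`` denotes an
    N-terminal modification.  Cysteine-site reporting is peptide-relative.
    """

    sequence: str
    modifications: tuple[Modification, ...] = ()
    accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= AMINO_ACIDS:
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        # canonical order (N-term first, then by position) so equality is
        # insensitive to construction order
        ordered = tuple(
            sorted(
                self.modifications,
                key=lambda m: (-1, m.name) if m.position == N_TERM else (m.position, m.name),
            )
        )
        object.__setattr__(self, "modifications", ordered)
        for mod in self.modifications:
            if mod.position != N_TERM:
                if not 1 <= mod.position <= len(self.sequence):
                    raise ValueError(
                        f"modification position {mod.position} outside peptide "
                        f"of length {len(self.sequence)}"
                    )
                residue = self.sequence[mod.position - 1]
                targets = MOD_MASS_TABLE[mod.name][0]
                if mod.name == IODOTMT and residue != "C":
                    raise ValueError("iodoTMT modification on non-cysteine residue")
                if mod.name != ITRAQ and residue not in targets:
                    raise ValueError(
                        f"{mod.name} does not target residue {residue!r}"
                    )

    @property
    def is_cysteine_containing(self) -> bool:
        return "C" in self.sequence

    @property
    def is_unique(self) -> bool:
        """True when the peptide maps to exactly one protein accession."""
        return len(self.accessions) == 1

    @property
    def is_iodo_labeled(self) -> bool:
        return any(m.name == IODOTMT for m in self.modifications)

    @property
    def cys_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "C")

    @property
    def labeled_cys_positions(self) -> tuple[int, ...]:
        return tuple(
            sorted(m.position for m in self.modifications if m.name == IODOTMT)
        )

    def key(self) -> str:
        """Stable identity string (annotated sequence + accessions)."""
        return f"{render_modified_sequence(self)}|{';'.join(self.accessions)}"


def parse_modified_sequence(
    annotated: str, accessions: Sequence[str] = ()
) -> ModifiedPeptide:
    """Parse a lowercase-marked peptide string into a :class:`ModifiedPeptide`.

    Marking rules (1-based positions):

    * lowercase ``c``                    -> iodoTMT6plex on that Cys
    * lowercase ``k``                    -> iTRAQ8plex on that Lys
    * lowercase ``m``                    -> oxidation on that Met
    * any other lowercase FIRST residue  -> iTRAQ8plex at the N-terminus
    * lowercase ``s``/``t``/``y`` later  -> phosphorylation
    * any other lowercase residue        -> :class:`PeptideParseError`

    >>> p = parse_modified_sequence("tcAQDEVLR", ["AT3G08030"])
    >>> p.sequence, p.labeled_cys_positions
    ('TCAQDEVLR', (2,))
    """
    if not annotated:
        raise PeptideParseError("empty peptide string")
    mods: list[Modification] = []
    for i, ch in enumerate(annotated, start=1):
        upper = ch.upper()
        if upper not in AMINO_ACIDS:
            raise PeptideParseError(
                f"invalid residue {ch!r} at position {i} in {annotated!r}"
            )
        if ch.isupper():
            continue
        if ch == "c":
            mods.append(Modification(i, IODOTMT))
        elif ch == "k":
            mods.append(Modification(i, ITRAQ))
        elif ch == "m":
            mods.append(Modification(i, OXIDATION))
        elif i == 1:
            mods.append(Modification(N_TERM, ITRAQ))
        elif ch in "sty":
            mods.append(Modification(i, PHOSPHO))
        else:
            raise PeptideParseError(
                f"lowercase residue {ch!r} at position {i} of {annotated!r} "
                "has no modification rule"
            )
    return ModifiedPeptide(
        sequence=annotated.upper(),
        modifications=tuple(mods),
        accessions=tuple(accessions),
    )


def render_modified_sequence(peptide: ModifiedPeptide) -> str:
    """Emit the lowercase-marked string for *peptide* (inverse of parsing).

    Faithful round-tripping requires the table convention: an N-terminal
    modification is rendered by lowercasing the first residue, so it is only
    unambiguous when the first residue is not itself a c/k/m target.
    """
    chars = list(peptide.sequence)
    for mod in peptide.modifications:
        idx = 0 if mod.position == N_TERM else mod.position - 1
        chars[idx] = chars[idx].lower()
    return "".join(chars)
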