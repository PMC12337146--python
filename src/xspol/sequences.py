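"""ssDNA sequence handling: parsing 5′→3′ strings and molar masses.

Oligonucleotide molar masses follow the 5′-OH, fully deprotonated
polyanion convention: the sum of 2′-deoxynucleotide residue masses minus
a 61.96 g/mol end-group correction and minus one proton (1.008 g/mol) per
phosphodiester linkage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .constants import END_GROUP_MASS, PROTON_MASS, RESIDUE_MASS

__all__ = ["SequenceRecord", "parse_sequence", "molar_mass"]

#: Characters stripped from decorated sequences such as "5′-CT-3′".
_DECORATIONS = "53'′-‐–′ \t"


@dataclass(frozen=True)
class SequenceRecord:
    """A single-stranded DNA sequence read 5′→3′.

    Attributes
    ----------
    sequence : str
        Upper-case bases from {A, C, G, T}.
    counts : dict
        Base → occurrence count.
    molar_mass : float
        Oligonucleotide molar mass, g/mol.
    """

    sequence: str
    counts: dict = field(default_factory=dict)
    molar_mass: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"5'-{self.sequence}-3'"


def _strip_decorations(text: str) -> str:
    """Remove 5′-/-3′ decorations (Unicode prime or ASCII quote) and spacing."""
    return text.strip().strip(_DECORATIONS)


def parse_sequence(text: str) -> SequenceRecord:
    """Parse an ssDNA string, optionally decorated as ``5′-…-3′``.

    Accepts the Unicode prime (U+2032), the ASCII apostrophe, or a bare
    sequence; case-insensitive.

    Raises
    ------
    ValueError
        If the sequence is empty after stripping decorations, or contains
        a character outside {A, C, G, T} (the offending position is
        reported).
    """
    if not isinstance(text, str):
        raise TypeError(f"expected str, got {type(text).__name__}")
    bare = _strip_decorations(text).upper()
    if not bare:
        raise ValueError(f"empty sequence in {text!r}")
    for i, ch in enumerate(bare):
        if ch not in RESIDUE_MASS:
            raise ValueError(
                f"unknown base {ch!r} at position {i} of {bare!r}; "
                "expected A, C, G or T"
            )
    counts = dict(Counter(bare))
    return SequenceRecord(sequence=bare, counts=counts, molar_mass=_mass(bare))


def _mass(bases: str) -> float:
    residues = sum(RESIDUE_MASS[b] for b in bases)
    return residues - END_GROUP_MASS - (len(bases) - 1) * PROTON_MASS


def molar_mass(seq: SequenceRecord | str) -> float:
    """Molar mass of an oligonucleotide, g/mol.

    ``M = Σ residue masses − 61.96 − (n−1)·1.008`` with residue masses
    dA 313.21, dC 289.18, dG 329.21, dT 304.2.
    """
    if isinstance(seq, str):
        seq = parse_sequence(seq)
    return _mass(seq.sequence)
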