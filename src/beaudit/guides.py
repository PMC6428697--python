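"""Guide RNA specification and small nucleotide-sequence helpers.

A guide is a 20-nt protospacer plus a PAM pattern (IUPAC, e.g. ``NGG``).
Editing-window positions are counted 1-based from the PAM-distal (5')
end of the protospacer, so the canonical cytosine-deaminase window is
positions 4-8.
"""

from __future__ import annotations

from dataclasses import dataclass

#: IUPAC nucleotide codes mapped to the set of concrete bases they match.
#: ``N`` matches any of A/C/G/T but never an ambiguous genome base.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def complement(seq: str) -> str:
    """Complement of *seq*, IUPAC-aware."""
    return seq.upper().translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of *seq*, IUPAC-aware."""
    return complement(seq)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True when every base of *seq* is matched by the IUPAC *pattern*.

    A genome base outside A/C/G/T (e.g. ``N``) matches nothing.
    """
    if len(pattern) != len(seq):
        return False
    for p, b in zip(pattern, seq):
        if b not in IUPAC_CODES.get(p, frozenset()):
            return False
    return True


@dataclass(frozen=True)
class GuideSpec:
    """A single guide RNA: protospacer, PAM pattern and editing window.

    Parameters
    ----------
    protospacer
        Guide-matching genomic sequence, 5'->3', PAM-proximal end last.
        A/C/G/T only.
    pam_pattern
        IUPAC pattern of the protospacer-adjacent motif, immediately 3'
        of the protospacer (``NGG`` for SpCas9-derived editors).
    editing_window
        Closed 1-based interval of protospacer positions, counted from
        the PAM-distal end, where deamination predominantly occurs.
    """

    protospacer: str
    pam_pattern: str = "NGG"
    editing_window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if not self.protospacer:
            raise ValueError("protospacer must be non-empty")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(
                f"protospacer contains non-ACGT characters: {self.protospacer!r}"
            )
        if not self.pam_pattern:
            raise ValueError("pam_pattern must be non-empty")
        if set(self.pam_pattern) - set(IUPAC_CODES):
            raise ValueError(
                f"pam_pattern contains non-IUPAC characters: {self.pam_pattern!r}"
            )
        lo, hi = self.editing_window
        if not (1 <= lo <= hi <= len(self.protospacer)):
            raise ValueError(
                f"editing_window {self.editing_window} outside protospacer "
                f"positions 1..{len(self.protospacer)}"
            )

    @property
    def length(self) -> int:
        """Protospacer length (20 for canonical guides)."""
        return len(self.protospacer)

    @property
    def site_length(self) -> int:
        """Length of protospacer + PAM, i.e. of a full target site."""
        return len(self.protospacer) + len(self.pam_pattern)

    def window_indices(self) -> range:
        """0-based protospacer indices covered by the editing window."""
        lo, hi = self.editing_window
        return range(lo - 1, hi)

    def window_editable_indices(self, base: str = "C") -> list[int]:
        """0-based window indices whose protospacer base equals *base*."""
        return [i for i in self.window_indices() if self.protospacer[i] == base]
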