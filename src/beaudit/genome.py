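"""Reference genome container with chromosome-vs-scaffold classification."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pyfaidx


@dataclass
class ReferenceGenome:
    """Named contigs with sequence and a scaffold flag.

    Contigs whose name starts with *scaffold_prefix* are treated as
    unplaced scaffolds; several downstream filters (notably the de novo
    structural-variant filter) discard events on scaffolds.
    """

    contigs: dict[str, str]
    scaffold_prefix: str = "scaffold"
    _order: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        self._order = {name: i for i, name in enumerate(self.contigs)}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def is_scaffold(self, name: str) -> bool:
        return name.startswith(self.scaffold_prefix)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self.contigs.values())

    def contig_index(self, name: str) -> int:
        """Stable ordering key for sorting genomic features."""
        return self._order[name]

    def base(self, contig: str, pos: int) -> str:
        """Base at 1-based position *pos* on *contig*."""
        return self.contigs[contig][pos - 1]

    def to_fasta(self, path: str | Path, line_width: int = 70) -> Path:
        """Write the genome as FASTA and build a .fai index alongside."""
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
        pyfaidx.Faidx(str(path)).close()
        return path

    @classmethod
    def from_fasta(cls, path: str | Path, scaffold_prefix: str = "scaffold") -> "ReferenceGenome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls(contigs=contigs, scaffold_prefix=scaffold_prefix)
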