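"""Variant-call containers and VCF 4.2 interchange.

The pipeline consumes caller output (GATK/SAMtools-style VCFs) rather
than producing calls itself.  Internally a call is a biallelic record;
multiallelic VCF records are decomposed on ingest so that
(contig, pos, ref, alt) keys are well defined.  Positions are 1-based
in this layer, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pysam

from .genome import ReferenceGenome

#: Site key: (contig, 1-based position, ref allele, alt allele)
SiteKey = tuple[str, int, str, str]

#: Largest ref/alt length difference still treated as a small indel.
MAX_SMALL_INDEL = 50


@dataclass(frozen=True)
class MemberCall:
    """One trio member's evidence at one site."""

    genotype: tuple[int, int] | None  # None = missing ('./.')
    depth: int
    pl: tuple[int, ...]
    callers: frozenset[str] = frozenset()

    def carries_alt(self) -> bool:
        return self.genotype is not None and 1 in self.genotype

    def is_het(self) -> bool:
        return self.genotype is not None and sorted(self.genotype) == [0, 1]


@dataclass(frozen=True)
class VariantCall:
    """A single-sample biallelic call."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    genotype: tuple[int, int] | None
    depth: int
    pl: tuple[int, ...]
    callers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_small_indel(self) -> bool:
        diff = abs(len(self.ref) - len(self.alt))
        return diff > 0 and diff < MAX_SMALL_INDEL

    def with_callers(self, callers: frozenset[str]) -> "VariantCall":
        return replace(self, callers=callers)


@dataclass(frozen=True)
class TrioGenotypes:
    """Offspring/sire/dam evidence joined at one site key."""

    contig: str
    pos: int
    ref: str
    alt: str
    offspring: MemberCall
    sire: MemberCall
    dam: MemberCall

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def member(self, role: str) -> MemberCall:
        return getattr(self, role)

    def offspring_call(self, sample_id: str = "offspring") -> VariantCall:
        m = self.offspring
        return VariantCall(
            contig=self.contig,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            sample_id=sample_id,
            genotype=m.genotype,
            depth=m.depth,
            pl=m.pl,
            callers=m.callers,
        )


TRIO_ROLES = ("offspring", "sire", "dam")


def _trio_header(genome: ReferenceGenome, samples: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in genome.lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    for s in samples:
        header.add_sample(s)
    return header


def write_trio_vcf(
    records: list[TrioGenotypes],
    genome: ReferenceGenome,
    path: str | Path,
    sample_names: tuple[str, str, str] = TRIO_ROLES,
) -> Path:
    """Write trio records as an uncompressed multi-sample VCF 4.2."""
    path = Path(path)
    header = _trio_header(genome, sample_names)
    ordered = sorted(
        records, key=lambda r: (genome.contig_index(r.contig), r.pos, r.ref, r.alt)
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in ordered:
            out = vcf.new_record(
                contig=rec.contig, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            for name, role in zip(sample_names, TRIO_ROLES):
                m = rec.member(role)
                fmt = out.samples[name]
                fmt["GT"] = m.genotype if m.genotype is not None else (None, None)
                fmt["DP"] = m.depth
                fmt["PL"] = list(m.pl)
            vcf.write(out)
    return path


def read_trio_vcf(
    path: str | Path,
    caller: str | None = None,
    sample_names: tuple[str, str, str] | None = None,
) -> list[TrioGenotypes]:
    """Read a multi-sample trio VCF, decomposing multiallelic records.

    Decomposition is naive: for alt allele *i*, genotype alleles equal
    to *i* become 1 and all other non-ref alleles collapse to 0; the PL
    vector is subset to the (0/0, 0/i, i/i) entries.
    """
    callers = frozenset([caller]) if caller else frozenset()
    records: list[TrioGenotypes] = []
    with pysam.VariantFile(str(path)) as vcf:
        names = sample_names or tuple(vcf.header.samples)
        if len(names) != 3:
            raise ValueError(f"expected 3 samples in {path}, got {names}")
        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts, start=1):
                members = {}
                for name, role in zip(names, TRIO_ROLES):
                    fmt = rec.samples[name]
                    gt = fmt.get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotype = None
                    else:
                        genotype = tuple(1 if a == i else 0 for a in gt)
                    depth = fmt.get("DP") or 0
                    pl_raw = fmt.get("PL")
                    if pl_raw is None:
                        pl = ()
                    elif len(alts) == 1:
                        pl = tuple(int(x) for x in pl_raw)
                    else:
                        # genotype index for alleles (j,k), j<=k: k(k+1)/2 + j
                        idx = [0, i * (i + 1) // 2, i * (i + 1) // 2 + i]
                        pl = tuple(int(pl_raw[j]) for j in idx)
                    members[role] = MemberCall(
                        genotype=genotype, depth=int(depth), pl=pl, callers=callers
                    )
                records.append(
                    TrioGenotypes(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        **members,
                    )
                )
    return records


def write_sites_vcf(
    keys: Iterable[SiteKey], genome: ReferenceGenome, path: str | Path
) -> Path:
    """Write a sites-only VCF (known-variant database interchange)."""
    path = Path(path)
    header = pysam.VariantHeader()
    for name, length in genome.lengths.items():
        header.contigs.add(name, length=length)
    ordered = sorted(keys, key=lambda k: (genome.contig_index(k[0]), k[1], k[2], k[3]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for contig, pos, ref, alt in ordered:
            rec = vcf.new_record(contig=contig, start=pos - 1, alleles=(ref, alt))
            vcf.write(rec)
    return path


def read_sites_vcf(path: str | Path) -> set[SiteKey]:
    """Read a sites-only VCF into an allele-aware key set."""
    keys: set[SiteKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                keys.add((rec.contig, rec.pos, rec.ref, alt))
    return keys


def write_calls_vcf(
    calls: list[VariantCall], genome: ReferenceGenome, path: str | Path
) -> Path:
    """Write single-sample calls (e.g. a final mutation set) as VCF."""
    path = Path(path)
    sample = calls[0].sample_id if calls else "sample"
    header = _trio_header(genome, [sample])
    ordered = sorted(calls, key=lambda c: (genome.contig_index(c.contig), c.pos, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in ordered:
            rec = vcf.new_record(contig=c.contig, start=c.pos - 1, alleles=(c.ref, c.alt))
            fmt = rec.samples[sample]
            fmt["GT"] = c.genotype if c.genotype is not None else (None, None)
            fmt["DP"] = c.depth
            if c.pl:
                fmt["PL"] = list(c.pl)
            vcf.write(rec)
    return path
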