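"""Genome-wide, PAM-aware, mismatch-tolerant guide target search.

Enumerates every locus, on both strands of every contig, where the PAM
pattern matches exactly (IUPAC-aware) and the protospacer aligns
ungapped with at most ``max_mismatches`` substitutions.  Mismatches are
counted over the protospacer only; a candidate whose PAM does not match
is rejected outright.  Windows containing an ambiguous genome base (N)
are rejected entirely, which keeps assembly gaps from producing
spurious sites.

Coordinates are 0-based half-open throughout (BED convention); the VCF
layer converts to 1-based positions at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import ReferenceGenome
from .guides import IUPAC_CODES, GuideSpec, complement, revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


@dataclass(frozen=True)
class OffTargetSite:
    """One candidate guide-homologous locus.

    ``start``/``end`` are 0-based half-open genomic coordinates covering
    protospacer + PAM.  ``site_sequence`` is protospacer-oriented
    (5'->3' with the PAM at the 3' end): for minus-strand sites it is
    the reverse complement of the genomic substring.
    ``mismatch_positions`` are 1-based protospacer positions counted
    from the PAM-distal end.
    """

    contig: str
    start: int
    end: int
    strand: str
    mismatch_count: int
    site_sequence: str
    mismatch_positions: tuple[int, ...]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pam_luts(pattern: str, complemented: bool) -> list[np.ndarray]:
    """Per-position boolean lookup tables over base codes 0..4.

    Code 4 (ambiguous base) never matches, including pattern 'N'.
    """
    luts = []
    for ch in pattern:
        allowed = IUPAC_CODES[complement(ch) if complemented else ch]
        lut = np.zeros(5, dtype=bool)
        for b in allowed:
            lut[_BASE_CODE[b]] = True
        luts.append(lut)
    return luts


def find_offtarget_sites(
    genome: ReferenceGenome, guide: GuideSpec, max_mismatches: int
) -> list[OffTargetSite]:
    """Enumerate all candidate target sites with <= *max_mismatches*.

    The on-target site itself (0 mismatches) is included; callers that
    want to audit off-targets only should exclude it by interval.
    Output is sorted by (contig order, start, strand).
    """
    if max_mismatches > guide.length:
        raise ValueError(
            f"max_mismatches ({max_mismatches}) exceeds protospacer length "
            f"({guide.length})"
        )
    if not genome.contigs:
        raise ValueError("genome has no contigs")

    L = guide.length
    P = len(guide.pam_pattern)
    W = L + P
    proto_codes = _encode(guide.protospacer)
    # minus-strand search compares the genomic plus-strand window against
    # the reverse complement of protospacer+PAM
    minus_proto_codes = _encode(revcomp(guide.protospacer))
    plus_pam = _pam_luts(guide.pam_pattern, complemented=False)
    minus_pam = _pam_luts(guide.pam_pattern[::-1], complemented=True)

    sites: list[OffTargetSite] = []
    for contig, seq in genome.contigs.items():
        if len(seq) < W:
            continue
        arr = _encode(seq)
        n = len(arr) - W + 1

        for strand in "+-":
            cand = np.ones(n, dtype=bool)
            if strand == "+":
                for j, lut in enumerate(plus_pam):
                    cand &= lut[arr[L + j : L + j + n]]
            else:
                for j, lut in enumerate(minus_pam):
                    cand &= lut[arr[j : j + n]]
            idx = np.nonzero(cand)[0]
            if idx.size == 0:
                continue
            win = arr[idx[:, None] + np.arange(W)[None, :]]
            clean = (win != 4).all(axis=1)
            if strand == "+":
                mm_cols = win[:, :L] != proto_codes[None, :]
            else:
                mm_cols = win[:, P:] != minus_proto_codes[None, :]
            mm = mm_cols.sum(axis=1)
            keep = clean & (mm <= max_mismatches)
            for row in np.nonzero(keep)[0]:
                start = int(idx[row])
                window = seq[start : start + W]
                cols = np.nonzero(mm_cols[row])[0]
                if strand == "+":
                    positions = tuple(int(c) + 1 for c in cols)
                    site_seq = window
                else:
                    # window column P+j maps to protospacer position L-j
                    positions = tuple(sorted(L - int(c) for c in cols))
                    site_seq = revcomp(window)
                sites.append(
                    OffTargetSite(
                        contig=contig,
                        start=start,
                        end=start + W,
                        strand=strand,
                        mismatch_count=int(mm[row]),
                        site_sequence=site_seq,
                        mismatch_positions=positions,
                    )
                )

    sites.sort(key=lambda s: (genome.contig_index(s.contig), s.start, s.strand))
    return sites


def sites_to_intervals(
    sites: list[OffTargetSite],
    flank: int = 0,
    genome: ReferenceGenome | None = None,
) -> list[tuple[str, int, int]]:
    """Merge sites into strand-collapsed genomic intervals (BED convention).

    Each site's [start, end) is extended by *flank* bp on both sides,
    clipped at contig ends when a genome is supplied, and overlapping or
    bookended intervals are merged.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        lo = max(0, s.start - flank)
        hi = s.end + flank
        if genome is not None:
            hi = min(hi, len(genome[s.contig]))
        by_contig.setdefault(s.contig, []).append((lo, hi))

    merged: list[tuple[str, int, int]] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig])
        cur_lo, cur_hi = ivs[0]
        for lo, hi in ivs[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                merged.append((contig, cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        merged.append((contig, cur_lo, cur_hi))
    return merged


def write_sites_bed(sites: list[OffTargetSite], path: str | Path) -> Path:
    """Write sites as BED6 (name and score carry the mismatch count)."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.start}\t{s.end}\tmm{s.mismatch_count}\t"
                f"{s.mismatch_count}\t{s.strand}\n"
            )
    return path


def write_sites_tsv(sites: list[OffTargetSite], path: str | Path) -> Path:
    """Write a detailed site table with sequences and mismatch positions."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "contig\tstart\tend\tstrand\tmismatch_count\tsite_sequence\t"
            "mismatch_positions\n"
        )
        for s in sites:
            pos = ",".join(map(str, s.mismatch_positions)) or "."
            fh.write(
                f"{s.contig}\t{s.start}\t{s.end}\t{s.strand}\t"
                f"{s.mismatch_count}\t{s.site_sequence}\t{pos}\n"
            )
    return path


def write_intervals_bed(
    intervals: list[tuple[str, int, int]], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for contig, lo, hi in intervals:
            fh.write(f"{contig}\t{lo}\t{hi}\n")
    return path


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return intervals
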