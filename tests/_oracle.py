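"""Independent brute-force oracles used by the test suite.

The sliding-window off-target scanner here is deliberately naive —
character-by-character comparison of every window on both strands —
and serves as the semantics ground truth for the indexed search in
the package.  It must stay independent of ``beaudit.offtargets``
internals (it only reuses the public site dataclass to make set
comparison possible).
"""

from __future__ import annotations

from beaudit.genome import ReferenceGenome
from beaudit.guides import IUPAC_CODES, GuideSpec, revcomp
from beaudit.offtargets import OffTargetSite


def brute_force_sites(
    genome: ReferenceGenome, guide: GuideSpec, max_mismatches: int
) -> set[OffTargetSite]:
    """Score every (L + PAM)-length window on both strands."""
    proto = guide.protospacer
    pam = guide.pam_pattern
    L = len(proto)
    W = L + len(pam)
    sites: set[OffTargetSite] = set()
    for contig, seq in genome.contigs.items():
        for start in range(len(seq) - W + 1):
            window = seq[start : start + W]
            if any(b not in "ACGT" for b in window):
                continue
            for strand in "+-":
                oriented = window if strand == "+" else revcomp(window)
                if not all(
                    oriented[L + j] in IUPAC_CODES[pam[j]] for j in range(len(pam))
                ):
                    continue
                mismatches = tuple(
                    i + 1 for i in range(L) if oriented[i] != proto[i]
                )
                if len(mismatches) <= max_mismatches:
                    sites.add(
                        OffTargetSite(
                            contig=contig,
                            start=start,
                            end=start + W,
                            strand=strand,
                            mismatch_count=len(mismatches),
                            site_sequence=oriented,
                            mismatch_positions=mismatches,
                        )
                    )
    return sites
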