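"""The off-target SNP filtering cascade.

Five ordered, composable filters over VCF-backed call sets:

1. caller intersection — keep calls reported by both variant callers;
2. known-database exclusion — drop calls present (allele-aware) in any
   known-SNP database;
3. parental-inheritance exclusion — drop offspring calls whose alt
   allele is carried by either parent in either caller's raw set;
4. C/G-substitution selection — keep SNPs whose reference base is C or
   G (the cytosine-deaminase signature covers C>N and its antisense
   G>N); a strict mode narrows this to C>T / G>A;
5. off-target interval intersection — keep calls falling inside the
   predicted guide-homologous intervals.

Each stage's input/output sizes are recorded in a :class:`FilterFunnel`
so the cascade can be audited stage by stage.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from .variants import SiteKey, TrioGenotypes, VariantCall

logger = logging.getLogger(__name__)

CASCADE_STAGES = (
    "caller_intersection",
    "known_db_exclusion",
    "parental_exclusion",
    "cg_substitution_selection",
    "offtarget_interval_intersection",
)


@dataclass
class FilterFunnel:
    """Ordered per-stage (name, n_in, n_out) bookkeeping."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: n_out {n_out} > n_in {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(
                f"stage {name}: n_in {n_in} != previous n_out {self.stages[-1][2]}"
            )
        self.stages.append((name, n_in, n_out))

    @property
    def counts(self) -> list[int]:
        """n_in of the first stage followed by every stage's n_out."""
        if not self.stages:
            return []
        return [self.stages[0][1]] + [s[2] for s in self.stages]

    def to_rows(self) -> list[dict]:
        return [
            {"stage": name, "n_in": n_in, "n_out": n_out, "n_dropped": n_in - n_out}
            for name, n_in, n_out in self.stages
        ]

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("stage\tn_in\tn_out\tn_dropped\n")
            for name, n_in, n_out in self.stages:
                fh.write(f"{name}\t{n_in}\t{n_out}\t{n_in - n_out}\n")
        return path


def intersect_callers(
    calls_a: list[VariantCall], calls_b: list[VariantCall]
) -> list[VariantCall]:
    """Keep calls reported by both callers at identical site keys.

    Genotype, depth and PL are taken from caller A (the primary
    caller); the callers field becomes the union.
    """
    keys_b: dict[SiteKey, VariantCall] = {c.key: c for c in calls_b}
    out = []
    for call in calls_a:
        match = keys_b.get(call.key)
        if match is not None:
            out.append(call.with_callers(call.callers | match.callers))
    return out


def exclude_known(
    calls: list[VariantCall], databases: list[set[SiteKey]]
) -> list[VariantCall]:
    """Drop calls whose (contig, pos, ref, alt) appears in any database.

    Matching is allele-aware: a novel alt allele at a database position
    is retained.
    """
    return [c for c in calls if not any(c.key in db for db in databases)]


def exclude_inherited(
    calls: list[VariantCall], parental_alt_keys: set[SiteKey]
) -> list[VariantCall]:
    """Drop offspring calls whose alt allele is carried by either parent.

    *parental_alt_keys* should be built from both parents' raw
    (pre-intersection) call sets so caller dropout in a parent cannot
    rescue an inherited variant.
    """
    return [c for c in calls if c.key not in parental_alt_keys]


def parental_alt_keys(trio_sets: list[list[TrioGenotypes]]) -> set[SiteKey]:
    """Site keys at which sire or dam carries the alt allele in any set."""
    keys: set[SiteKey] = set()
    for records in trio_sets:
        for rec in records:
            if rec.sire.carries_alt() or rec.dam.carries_alt():
                keys.add(rec.key)
    return keys


def select_cg_substitutions(
    calls: list[VariantCall], strict_bisulfite_signature: bool = False
) -> list[VariantCall]:
    """Keep SNPs whose reference base is C or G.

    Deaminase editing converts C:G pairs, read out as C>N on one strand
    and G>N on the other.  With ``strict_bisulfite_signature`` only the
    canonical C>T / G>A products are kept.  Non-SNP records are dropped
    with a logged count.
    """
    snps = [c for c in calls if c.is_snp]
    n_non_snp = len(calls) - len(snps)
    if n_non_snp:
        logger.info("select_cg_substitutions: dropped %d non-SNP records", n_non_snp)
    if strict_bisulfite_signature:
        return [
            c
            for c in snps
            if (c.ref == "C" and c.alt == "T") or (c.ref == "G" and c.alt == "A")
        ]
    return [c for c in snps if c.ref in ("C", "G")]


def intersect_with_offtargets(
    calls: list[VariantCall], intervals: list[tuple[str, int, int]]
) -> list[VariantCall]:
    """Keep calls whose position falls inside a predicted off-target interval.

    Intervals are BED-convention (0-based half-open) and must be
    merged; a 1-based call position matches when pos-1 lies in
    [start, end).
    """
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for contig, lo, hi in sorted(intervals):
        starts.setdefault(contig, []).append(lo)
        ends.setdefault(contig, []).append(hi)

    missing_contigs: set[str] = set()
    out = []
    for call in calls:
        if call.contig not in starts:
            if call.contig not in missing_contigs:
                missing_contigs.add(call.contig)
                logger.info(
                    "intersect_with_offtargets: contig %s absent from interval set",
                    call.contig,
                )
            continue
        p = call.pos - 1
        i = bisect_right(starts[call.contig], p) - 1
        if i >= 0 and p < ends[call.contig][i]:
            out.append(call)
    return out


def run_offtarget_cascade(
    trio_a: list[TrioGenotypes],
    trio_b: list[TrioGenotypes],
    databases: list[set[SiteKey]],
    intervals: list[tuple[str, int, int]],
    offspring_id: str = "offspring",
    strict_bisulfite_signature: bool = False,
) -> tuple[list[VariantCall], FilterFunnel]:
    """Run the full five-stage off-target audit on one trio.

    *trio_a*/*trio_b* are the two callers' trio call sets; *databases*
    the known-SNP site-key sets; *intervals* the merged off-target
    intervals predicted for the guide.  Returns the surviving offspring
    calls and the per-stage funnel.
    """
    calls_a = [r.offspring_call(offspring_id) for r in trio_a if r.offspring.carries_alt()]
    calls_b = [r.offspring_call(offspring_id) for r in trio_b if r.offspring.carries_alt()]

    funnel = FilterFunnel()
    s1 = intersect_callers(calls_a, calls_b)
    funnel.add("caller_intersection", len(calls_a), len(s1))

    s2 = exclude_known(s1, databases)
    funnel.add("known_db_exclusion", len(s1), len(s2))

    inherited = parental_alt_keys([trio_a, trio_b])
    s3 = exclude_inherited(s2, inherited)
    funnel.add("parental_exclusion", len(s2), len(s3))

    s4 = select_cg_substitutions(s3, strict_bisulfite_signature)
    funnel.add("cg_substitution_selection", len(s3), len(s4))

    s5 = intersect_with_offtargets(s4, intervals)
    funnel.add("offtarget_interval_intersection", len(s4), len(s5))

    return s5, funnel
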