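"""Trio-based de novo mutation calling, SV filtering and kinship checks.

De novo SNPs/indels are offspring variants absent from both parents
that survive depth and Phred-scaled-likelihood (PL) filters.  The
final manual-curation step used in trio resequencing studies is
replaced here by an explicit, reproducible "review" flag (clustered
candidates and homopolymer-run sites are flagged, never dropped).

De novo structural variants are founder-specific BreakDancer-style
events after removing founder-shared SVs, low-support SVs and events
on unplaced scaffolds.  Pedigree integrity is checked with the
KING-robust pairwise kinship estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import FilterFunnel, parental_alt_keys
from .genome import ReferenceGenome
from .variants import SiteKey, TrioGenotypes

logger = logging.getLogger(__name__)

DNM_STAGES = (
    "caller_intersection",
    "known_db_exclusion",
    "mendelian_candidates",
    "depth_pl_filters",
)


@dataclass(frozen=True)
class DnmFilterParams:
    """Depth and PL thresholds for de novo candidates.

    ``min_depth_each_member`` applies to offspring, sire and dam.
    ``min_pl_second_best_offspring`` requires the offspring's call to be
    confidently non-ambiguous: every PL entry other than the called
    genotype's (which is 0) must be at least this large.
    ``min_pl_homref_parents`` requires each parent's alt-carrying
    genotypes to be confidently rejected.
    """

    min_depth_each_member: int = 10
    min_pl_second_best_offspring: int = 20
    min_pl_homref_parents: int = 20

    def __post_init__(self) -> None:
        if min(
            self.min_depth_each_member,
            self.min_pl_second_best_offspring,
            self.min_pl_homref_parents,
        ) < 0:
            raise ValueError("DnmFilterParams thresholds must be >= 0")


@dataclass(frozen=True)
class StructuralVariant:
    """A BreakDancer-style structural-variant call."""

    contig: str
    start: int
    end: int
    sv_type: str  # DEL, INS, INV, ITX, CTX
    supporting_reads: int
    local_depth: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "INS", "INV", "ITX", "CTX"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type in ("DEL", "INS", "INV") and not self.start < self.end:
            raise ValueError(f"start must be < end for {self.sv_type}")
        if self.supporting_reads < 0 or self.local_depth < 0:
            raise ValueError("supporting_reads and local_depth must be >= 0")

    @property
    def support_fraction(self) -> float:
        if self.local_depth == 0:
            return 0.0
        return self.supporting_reads / self.local_depth


def mendelian_denovo_candidates(
    trio_sites: list[TrioGenotypes],
) -> tuple[list[TrioGenotypes], int]:
    """Sites where the offspring carries an alt allele absent from both parents.

    Sites with a missing parent genotype cannot be certified de novo;
    they are excluded and counted separately (second return value).
    """
    candidates = []
    n_unresolvable = 0
    for rec in trio_sites:
        if not rec.offspring.carries_alt():
            continue
        if rec.sire.genotype is None or rec.dam.genotype is None:
            n_unresolvable += 1
            continue
        if not rec.sire.carries_alt() and not rec.dam.carries_alt():
            candidates.append(rec)
    return candidates, n_unresolvable


def apply_dnm_filters(
    candidates: list[TrioGenotypes], params: DnmFilterParams
) -> list[TrioGenotypes]:
    """Depth/PL filtering of de novo candidates (all three members)."""
    out = []
    for rec in candidates:
        members = (rec.offspring, rec.sire, rec.dam)
        if any(m.depth < params.min_depth_each_member for m in members):
            continue
        off = rec.offspring
        if off.genotype is None or not off.pl:
            continue
        called_idx = sum(off.genotype)  # biallelic PL order: 0/0, 0/1, 1/1
        others = [p for i, p in enumerate(off.pl) if i != called_idx]
        if others and min(others) < params.min_pl_second_best_offspring:
            continue
        parents_ok = True
        for parent in (rec.sire, rec.dam):
            if not parent.pl:
                continue
            # alt-carrying genotypes are PL indices 1 (het) and 2 (hom-alt)
            alt_pls = parent.pl[1:]
            if alt_pls and min(alt_pls) < params.min_pl_homref_parents:
                parents_ok = False
                break
        if parents_ok:
            out.append(rec)
    return out


def flag_for_review(
    candidates: list[TrioGenotypes],
    genome: ReferenceGenome | None = None,
    cluster_distance: int = 5,
    homopolymer_min_run: int = 6,
) -> dict[SiteKey, list[str]]:
    """Reproducible stand-in for manual curation: flag, never drop.

    A candidate is flagged ``clustered`` when another candidate lies
    within *cluster_distance* bp, and ``homopolymer`` when it falls in
    a reference homopolymer run of *homopolymer_min_run* bp or more.
    """
    flags: dict[SiteKey, list[str]] = {rec.key: [] for rec in candidates}
    by_contig: dict[str, list[TrioGenotypes]] = {}
    for rec in candidates:
        by_contig.setdefault(rec.contig, []).append(rec)
    for contig, recs in by_contig.items():
        recs.sort(key=lambda r: r.pos)
        for i, rec in enumerate(recs):
            near = (
                i > 0
                and rec.pos - recs[i - 1].pos <= cluster_distance
            ) or (
                i + 1 < len(recs)
                and recs[i + 1].pos - rec.pos <= cluster_distance
            )
            if near:
                flags[rec.key].append("clustered")
        if genome is None or contig not in genome:
            continue
        seq = genome[contig]
        for rec in recs:
            i = rec.pos - 1
            base = seq[i]
            run = 1
            j = i - 1
            while j >= 0 and seq[j] == base:
                run += 1
                j -= 1
            j = i + 1
            while j < len(seq) and seq[j] == base:
                run += 1
                j += 1
            if run >= homopolymer_min_run:
                flags[rec.key].append("homopolymer")
    return flags


def run_denovo_pipeline(
    trio_a: list[TrioGenotypes],
    trio_b: list[TrioGenotypes],
    databases: list[set[SiteKey]],
    params: DnmFilterParams | None = None,
    genome: ReferenceGenome | None = None,
) -> tuple[list[TrioGenotypes], dict[SiteKey, list[str]], FilterFunnel]:
    """Full de novo SNP/indel pipeline on one trio.

    Stages: caller intersection -> known-database exclusion ->
    Mendelian candidate selection -> depth/PL filters.  Review flags
    are attached afterwards.  Returns (calls, flags, funnel); SNPs and
    indels can be split with :func:`split_snps_indels`.
    """
    params = params or DnmFilterParams()

    a_by_key = {r.key: r for r in trio_a if r.offspring.carries_alt()}
    b_keys = {r.key for r in trio_b if r.offspring.carries_alt()}
    funnel = FilterFunnel()

    s1 = [a_by_key[k] for k in a_by_key if k in b_keys]
    funnel.add("caller_intersection", len(a_by_key), len(s1))

    s2 = [r for r in s1 if not any(r.key in db for db in databases)]
    funnel.add("known_db_exclusion", len(s1), len(s2))

    # parental exclusion is conservative: an alt seen in a parent in
    # EITHER caller's raw set disqualifies the site
    inherited = parental_alt_keys([trio_a, trio_b])
    mendelian, n_unresolvable = mendelian_denovo_candidates(s2)
    if n_unresolvable:
        logger.info("denovo: %d sites with missing parent genotype excluded", n_unresolvable)
    s3 = [r for r in mendelian if r.key not in inherited]
    funnel.add("mendelian_candidates", len(s2), len(s3))

    s4 = apply_dnm_filters(s3, params)
    funnel.add("depth_pl_filters", len(s3), len(s4))

    flags = flag_for_review(s4, genome=genome)
    s4_sorted = sorted(s4, key=lambda r: (r.contig, r.pos, r.alt))
    return s4_sorted, flags, funnel


def split_snps_indels(
    records: list[TrioGenotypes],
) -> tuple[list[TrioGenotypes], list[TrioGenotypes]]:
    snps = [r for r in records if r.is_snp]
    indels = [r for r in records if not r.is_snp]
    return snps, indels


# ---------------------------------------------------------------------------
# Structural variants


def _reciprocal_overlap(a: StructuralVariant, b: StructuralVariant) -> float:
    if a.contig != b.contig:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def denovo_svs(
    founder_svs: dict[str, list[StructuralVariant]],
    genome: ReferenceGenome,
    min_support_fraction: float = 0.5,
    min_reciprocal_overlap: float = 0.5,
) -> dict[str, list[StructuralVariant]]:
    """Founder-specific SVs after the three removal rules.

    Removes, per animal: (a) SVs reciprocally overlapping (>= 50%
    reciprocal overlap, same type) an SV in any other founder; (b) SVs
    whose supporting-read fraction of local depth is below
    *min_support_fraction*; (c) SVs on scaffold contigs.
    """
    animals = list(founder_svs)
    if len(animals) < 2:
        warnings.warn(
            "single founder: founder-commonality rule skipped", stacklevel=2
        )
    out: dict[str, list[StructuralVariant]] = {}
    for animal in animals:
        kept = []
        for sv in founder_svs[animal]:
            if genome.is_scaffold(sv.contig):
                continue
            if sv.support_fraction < min_support_fraction:
                continue
            common = any(
                other.sv_type == sv.sv_type
                and _reciprocal_overlap(sv, other) >= min_reciprocal_overlap
                for other_animal in animals
                if other_animal != animal
                for other in founder_svs[other_animal]
            )
            if common:
                continue
            kept.append(sv)
        out[animal] = kept
    return out


def read_sv_table(path: str | Path, sample_id: str | None = None) -> list[StructuralVariant]:
    """Read a BreakDancer-like tab-separated SV table."""
    svs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            svs.append(
                StructuralVariant(
                    contig=f[idx["chrom"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    sv_type=f[idx["type"]],
                    supporting_reads=int(f[idx["supporting_reads"]]),
                    local_depth=int(f[idx["depth"]]),
                    sample_id=sample_id or f[idx.get("sample", idx["chrom"])],
                )
            )
    return svs


def write_sv_table(svs: list[StructuralVariant], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tsupporting_reads\tdepth\tsample\n")
        for sv in svs:
            fh.write(
                f"{sv.contig}\t{sv.start}\t{sv.end}\t{sv.sv_type}\t"
                f"{sv.supporting_reads}\t{sv.local_depth}\t{sv.sample_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Kinship


def pairwise_kinship(
    genotypes: np.ndarray, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """KING-robust kinship coefficients for all sample pairs.

    *genotypes* is an (n_sites, n_samples) array of alt-allele counts
    (0/1/2; negative = missing, dropped pairwise).  For samples i, j:

        phi = (N_HetHet - 2 * N_AA,aa) / (N_Het(i) + N_Het(j))

    where ``N_HetHet`` counts sites at which both are heterozygous,
    ``N_AA,aa`` sites at which they are opposite homozygotes, and
    ``N_Het(.)`` each sample's heterozygous sites (over the pairwise
    complete sites).  A zero denominator yields NaN.  The diagonal is
    the estimator's self-kinship, 0.5.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotypes must be a 2-D (sites x samples) array")
    n_samples = g.shape[1]
    ids = sample_ids or [f"sample{i}" for i in range(n_samples)]
    if len(ids) != n_samples:
        raise ValueError("sample_ids length does not match genotype columns")

    phi = np.full((n_samples, n_samples), np.nan)
    for i in range(n_samples):
        for j in range(i, n_samples):
            gi, gj = g[:, i], g[:, j]
            valid = (gi >= 0) & (gj >= 0)
            gi, gj = gi[valid], gj[valid]
            n_hethet = int(np.sum((gi == 1) & (gj == 1)))
            n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
            denom = int(np.sum(gi == 1)) + int(np.sum(gj == 1))
            if denom > 0:
                phi[i, j] = phi[j, i] = (n_hethet - 2 * n_opp) / denom
    return pd.DataFrame(phi, index=ids, columns=ids)


def genotype_matrix(
    trio_sets: list[list[TrioGenotypes]], snps_only: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Alt-allele-count matrix (sites x [offspring, sire, dam]) from trio records.

    Sites absent from a record set are hom-ref by construction of
    variant-only call sets.  Intended for the kinship check, which
    needs shared biallelic SNP genotypes.
    """
    keys: set[SiteKey] = set()
    per_set: list[dict[SiteKey, TrioGenotypes]] = []
    for records in trio_sets:
        d = {r.key: r for r in records if (r.is_snp or not snps_only)}
        per_set.append(d)
        keys.update(d)
    ordered = sorted(keys)
    rows = []
    for key in ordered:
        rec = next((d[key] for d in per_set if key in d), None)
        counts = []
        for role in ("offspring", "sire", "dam"):
            m = rec.member(role)
            counts.append(sum(m.genotype) if m.genotype is not None else -1)
        rows.append(counts)
    return np.array(rows, dtype=int), ["offspring", "sire", "dam"]
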