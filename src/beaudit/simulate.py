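"""Synthetic data with known ground truth for the audit pipeline.

Generates every input the pipeline consumes: a toy reference genome
with chromosome and scaffold contigs, planted guide-homologous loci,
trio call sets from two emulated callers, known-SNP databases,
founder structural-variant tables and amplicon read pools.  All
generators are pure functions of (config, seed): the same
configuration always yields byte-identical outputs.

The two "callers" are emulated by independently thinning one master
call set — the intersection logic downstream is what is under test,
not the callers themselves.  Spiked categories (inherited, database
-known, de novo SNPs/indels, off-target C>T edits) never share a
position, and non-off-target variants are placed outside the guide's
predicted off-target intervals so that spike-in recovery is exact
under zero noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genome import ReferenceGenome
from .guides import GuideSpec, revcomp
from .offtargets import find_offtarget_sites, sites_to_intervals
from .trio import StructuralVariant, write_sv_table
from .variants import (
    MemberCall,
    SiteKey,
    TrioGenotypes,
    write_sites_vcf,
    write_trio_vcf,
)

#: Default synthetic guide: 20-nt protospacer with editable cytosines in
#: the canonical editing window (positions 4 and 5 from the PAM-distal
#: end), NGG PAM.
DEFAULT_GUIDE = GuideSpec(protospacer="GATCCAGTTGAGCTAAGCTA")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: minimum spacing between spiked variant positions (> max indel length)
_SITE_SPACING = 30


class ConfigurationError(ValueError):
    pass


class CapacityError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic trio and amplicon data.

    Counts are numbers of spiked sites; proportions are in [0, 1].
    ``mean_depth`` mirrors ~37x trio WGS coverage; de novo SNP/indel
    counts sit in the range observed in edited-animal trios; the
    default has no spiked off-target edits (the expected outcome for a
    specific guide) and no noise, so downstream output can be compared
    with ground truth exactly.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_contigs: int = 4
    scaffold_fraction: float = 0.25
    n_inherited_snps: int = 2000
    n_db_known_snps: int = 400
    n_denovo_snps: int = 20
    n_denovo_indels: int = 10
    n_offtarget_edits: int = 0
    offtarget_max_mismatches: int = 5
    mean_depth: float = 37.0
    caller_discordance_rate: float = 0.0
    amplicon_edit_fraction: float = 0.3
    amplicon_indel_fraction: float = 0.25
    amplicon_n_reads: int = 10_000
    sequencing_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "scaffold_fraction",
            "caller_discordance_rate",
            "amplicon_edit_fraction",
            "amplicon_indel_fraction",
            "sequencing_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_contigs",
            "n_inherited_snps",
            "n_db_known_snps",
            "n_denovo_snps",
            "n_denovo_indels",
            "n_offtarget_edits",
            "offtarget_max_mismatches",
            "amplicon_n_reads",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_contigs == 0:
            raise ConfigurationError("n_contigs must be >= 1")
        if self.genome_length < 1000:
            raise ConfigurationError(
                f"genome_length must be >= 1000, got {self.genome_length}"
            )
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        if self.amplicon_edit_fraction + self.amplicon_indel_fraction > 1.0:
            raise ConfigurationError(
                "amplicon_edit_fraction + amplicon_indel_fraction must be <= 1"
            )


@dataclass
class GroundTruth:
    """Spiked-site bookkeeping for recovery tests.

    Site entries are dicts with contig/pos/ref/alt plus, for offspring
    -only categories, an ``in_both_callers`` flag recording whether the
    record survived caller thinning in both emulated callers.
    """

    denovo_snp_sites: list[dict] = field(default_factory=list)
    denovo_indel_sites: list[dict] = field(default_factory=list)
    offtarget_edit_sites: list[dict] = field(default_factory=list)
    inherited_sites: list[dict] = field(default_factory=list)
    db_known_sites: list[dict] = field(default_factory=list)
    true_amplicon_fractions: dict = field(default_factory=dict)

    def keys(self, category: str) -> set[SiteKey]:
        return {
            (d["contig"], d["pos"], d["ref"], d["alt"])
            for d in getattr(self, category)
        }

    def both_caller_keys(self, category: str) -> set[SiteKey]:
        return {
            (d["contig"], d["pos"], d["ref"], d["alt"])
            for d in getattr(self, category)
            if d.get("in_both_callers", True)
        }

    def all_site_keys(self) -> list[SiteKey]:
        out = []
        for cat in (
            "denovo_snp_sites",
            "denovo_indel_sites",
            "offtarget_edit_sites",
            "inherited_sites",
            "db_known_sites",
        ):
            out.extend(sorted(self.keys(cat)))
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config_seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, salt])


def simulate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Uniform-composition contigs; a scaffold_fraction of them flagged.

    Contig lengths split ``genome_length`` as evenly as possible;
    chromosome-like contigs are named ``chr1..``, scaffolds
    ``scaffold_1..``.
    """
    rng = _rng(config.seed, 1)
    n = config.n_contigs
    base_len = config.genome_length // n
    lengths = [base_len] * n
    lengths[-1] += config.genome_length - base_len * n
    n_scaffolds = round(config.scaffold_fraction * n)
    contigs: dict[str, str] = {}
    for i, length in enumerate(lengths):
        if i < n - n_scaffolds:
            name = f"chr{i + 1}"
        else:
            name = f"scaffold_{i - (n - n_scaffolds) + 1}"
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        contigs[name] = seq
    return ReferenceGenome(contigs=contigs)


def plant_offtarget_homologs(
    genome: ReferenceGenome,
    guide: GuideSpec,
    n: int,
    mismatches_per_site: list[int],
    seed: int,
) -> tuple[ReferenceGenome, list[tuple[str, int, int, str, int]]]:
    """Write n guide homologs into the genome at random loci and strands.

    Each planted locus carries the protospacer with exactly the
    requested number of substitutions (never in the PAM, which is made
    concrete and pattern-matching) so a mismatch-tolerant search must
    recover it.  Returns the modified genome and the planted intervals
    as (contig, start, end, strand, n_mismatches).
    """
    if len(mismatches_per_site) != n:
        raise ValueError("mismatches_per_site must have length n")
    if any(m > guide.length or m < 0 for m in mismatches_per_site):
        raise ValueError(
            f"mismatch counts must be in 0..{guide.length}: {mismatches_per_site}"
        )
    rng = np.random.default_rng([seed, 2])
    W = guide.site_length
    contigs = dict(genome.contigs)
    names = [c for c in contigs if len(contigs[c]) >= W + 2]
    if not names:
        raise CapacityError("no contig long enough to plant a site")
    weights = np.array([len(contigs[c]) for c in names], dtype=float)
    weights /= weights.sum()

    planted: list[tuple[str, int, int, str, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    for m in mismatches_per_site:
        placed = False
        for _ in range(1000):
            contig = str(rng.choice(names, p=weights))
            start = int(rng.integers(0, len(contigs[contig]) - W + 1))
            if any(start < hi + W and start + W > lo - W for lo, hi in occupied[contig]):
                continue
            # build the site sequence: concrete PAM + mismatched protospacer
            proto = list(guide.protospacer)
            mm_idx = rng.choice(guide.length, size=m, replace=False)
            for i in mm_idx:
                choices = [b for b in "ACGT" if b != proto[i]]
                proto[i] = choices[int(rng.integers(0, 3))]
            pam = []
            from .guides import IUPAC_CODES

            for ch in guide.pam_pattern:
                allowed = sorted(IUPAC_CODES[ch])
                pam.append(allowed[int(rng.integers(0, len(allowed)))])
            site = "".join(proto) + "".join(pam)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = site if strand == "+" else revcomp(site)
            seq = contigs[contig]
            contigs[contig] = seq[:start] + insert + seq[start + W :]
            occupied[contig].append((start, start + W))
            planted.append((contig, start, start + W, strand, int(m)))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place a homolog with {m} mismatches after 1000 tries"
            )
    return ReferenceGenome(contigs=contigs, scaffold_prefix=genome.scaffold_prefix), planted


def _sample_positions(
    genome: ReferenceGenome,
    n: int,
    rng: np.random.Generator,
    forbidden: list[tuple[str, int, int]],
    taken: dict[str, list[int]],
    margin: int = 40,
) -> list[tuple[str, int]]:
    """n distinct (contig, 1-based pos) with spacing and exclusion zones."""
    names = list(genome.contigs)
    weights = np.array([len(genome[c]) for c in names], dtype=float)
    weights /= weights.sum()
    forb: dict[str, list[tuple[int, int]]] = {}
    for contig, lo, hi in forbidden:
        forb.setdefault(contig, []).append((lo - margin, hi + margin))
    out = []
    for _ in range(n):
        for attempt in range(2000):
            contig = str(rng.choice(names, p=weights))
            length = len(genome[contig])
            if length <= 2 * margin:
                continue
            pos = int(rng.integers(margin, length - margin)) + 1  # 1-based
            if any(lo < pos <= hi for lo, hi in forb.get(contig, [])):
                continue
            near = any(
                abs(pos - q) < _SITE_SPACING for q in taken.setdefault(contig, [])
            )
            if near:
                continue
            taken[contig].append(pos)
            out.append((contig, pos))
            break
        else:
            raise CapacityError(
                f"could not place {n} sites without collision (placed {len(out)})"
            )
    return out


def _member(
    genotype: tuple[int, int], rng: np.random.Generator, mean_depth: float
) -> MemberCall:
    depth = int(rng.poisson(mean_depth))
    # PL: 0 for the called genotype, 40-255 scaled by depth elsewhere
    other = int(min(255, 40 + 3 * depth))
    idx = sum(genotype)
    pl = tuple(0 if i == idx else other for i in range(3))
    return MemberCall(genotype=genotype, depth=depth, pl=pl)


def _transmit(parent: tuple[int, int], rng: np.random.Generator) -> int:
    return parent[int(rng.integers(0, 2))]


def simulate_trio_calls(
    genome: ReferenceGenome,
    config: SimulationConfig,
    guide: GuideSpec | None = None,
    planted_intervals: list[tuple[str, int, int]] | None = None,
) -> tuple[list[TrioGenotypes], list[TrioGenotypes], GroundTruth]:
    """Two callers' trio call sets plus ground truth.

    When a guide is given, its off-target intervals (at
    ``offtarget_max_mismatches``) are computed on *genome*; off-target
    C>T/G>A edits are spiked inside them and every other category is
    kept outside them.  ``caller_discordance_rate`` of records are
    dropped from exactly one (randomly chosen) caller.
    """
    rng = _rng(config.seed, 3)

    if guide is not None and planted_intervals is None:
        sites = find_offtarget_sites(genome, guide, config.offtarget_max_mismatches)
        planted_intervals = sites_to_intervals(sites, genome=genome)
    intervals = planted_intervals or []
    if config.n_offtarget_edits > 0 and not intervals:
        raise CapacityError(
            "off-target edits requested but no off-target intervals available"
        )

    taken: dict[str, list[int]] = {}
    truth = GroundTruth()
    records: list[tuple[TrioGenotypes, str]] = []  # (record, category)

    def genome_base(contig: str, pos: int) -> str:
        return genome[contig][pos - 1]

    # inherited + database-known SNPs: segregating sites, HWE parents,
    # Mendelian transmission; sites where nobody carries the alt yield
    # no VCF record, as a variant-only caller would emit
    n_seg = config.n_inherited_snps + config.n_db_known_snps
    seg_positions = _sample_positions(genome, n_seg, rng, intervals, taken)
    for i, (contig, pos) in enumerate(seg_positions):
        ref = genome_base(contig, pos)
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        q = float(rng.uniform(0.2, 0.8))
        sire = tuple(sorted(int(rng.random() < q) for _ in range(2)))
        dam = tuple(sorted(int(rng.random() < q) for _ in range(2)))
        child = tuple(sorted((_transmit(sire, rng), _transmit(dam, rng))))
        entry = {"contig": contig, "pos": pos, "ref": ref, "alt": alt}
        is_db = i >= config.n_inherited_snps
        (truth.db_known_sites if is_db else truth.inherited_sites).append(entry)
        if sire == (0, 0) and dam == (0, 0) and child == (0, 0):
            continue
        rec = TrioGenotypes(
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            offspring=_member(child, rng, config.mean_depth),
            sire=_member(sire, rng, config.mean_depth),
            dam=_member(dam, rng, config.mean_depth),
        )
        records.append((rec, "db" if is_db else "inherited"))

    homref = (0, 0)
    het = (0, 1)

    # de novo SNPs: offspring-only heterozygous substitutions
    for contig, pos in _sample_positions(
        genome, config.n_denovo_snps, rng, intervals, taken
    ):
        ref = genome_base(contig, pos)
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        truth.denovo_snp_sites.append(
            {"contig": contig, "pos": pos, "ref": ref, "alt": alt}
        )
        rec = TrioGenotypes(
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            offspring=_member(het, rng, config.mean_depth),
            sire=_member(homref, rng, config.mean_depth),
            dam=_member(homref, rng, config.mean_depth),
        )
        records.append((rec, "dnm_snp"))

    # de novo indels: 1-23 bp insertions or deletions, VCF-anchored
    for contig, pos in _sample_positions(
        genome, config.n_denovo_indels, rng, intervals, taken
    ):
        length = int(rng.integers(1, 24))
        anchor = genome_base(contig, pos)
        if rng.random() < 0.5 and pos + length <= len(genome[contig]):
            ref = genome[contig][pos - 1 : pos - 1 + length + 1]
            alt = anchor
        else:
            ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            ref = anchor
            alt = anchor + ins
        truth.denovo_indel_sites.append(
            {"contig": contig, "pos": pos, "ref": ref, "alt": alt}
        )
        rec = TrioGenotypes(
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            offspring=_member(het, rng, config.mean_depth),
            sire=_member(homref, rng, config.mean_depth),
            dam=_member(homref, rng, config.mean_depth),
        )
        records.append((rec, "dnm_indel"))

    # off-target edits: C>T (or G>A) inside predicted off-target intervals
    edit_positions: list[tuple[str, int, str, str, tuple[str, int, int]]] = []
    if config.n_offtarget_edits > 0:
        candidates = []
        for contig, lo, hi in intervals:
            for p in range(lo + 1, hi + 1):  # 1-based positions in interval
                base = genome_base(contig, p)
                if base in "CG" and all(
                    abs(p - q) >= _SITE_SPACING for q in taken.get(contig, [])
                ):
                    candidates.append((contig, p, base, (contig, lo, hi)))
        if len(candidates) < config.n_offtarget_edits:
            raise CapacityError(
                "not enough editable C/G positions inside off-target intervals"
            )
        chosen = rng.choice(len(candidates), size=config.n_offtarget_edits, replace=False)
        for ci in sorted(int(c) for c in chosen):
            contig, p, base, interval = candidates[ci]
            alt = "T" if base == "C" else "A"
            taken.setdefault(contig, []).append(p)
            edit_positions.append((contig, p, base, alt, interval))
    for contig, pos, ref, alt, interval in edit_positions:
        truth.offtarget_edit_sites.append(
            {
                "contig": contig,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "source_offtarget_interval": list(interval),
            }
        )
        rec = TrioGenotypes(
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            offspring=_member(het, rng, config.mean_depth),
            sire=_member(homref, rng, config.mean_depth),
            dam=_member(homref, rng, config.mean_depth),
        )
        records.append((rec, "offtarget"))

    # caller thinning: each record drops out of exactly one caller with
    # probability caller_discordance_rate
    caller_a: list[TrioGenotypes] = []
    caller_b: list[TrioGenotypes] = []
    truth_by_key = {
        (d["contig"], d["pos"], d["ref"], d["alt"]): d
        for cat in (
            truth.denovo_snp_sites,
            truth.denovo_indel_sites,
            truth.offtarget_edit_sites,
        )
        for d in cat
    }
    for rec, _category in records:
        drop_a = drop_b = False
        if rng.random() < config.caller_discordance_rate:
            if rng.random() < 0.5:
                drop_a = True
            else:
                drop_b = True
        if not drop_a:
            caller_a.append(_with_caller(rec, "callerA"))
        if not drop_b:
            caller_b.append(_with_caller(rec, "callerB"))
        entry = truth_by_key.get(rec.key)
        if entry is not None:
            entry["in_both_callers"] = not (drop_a or drop_b)

    return caller_a, caller_b, truth


def _with_caller(rec: TrioGenotypes, caller: str) -> TrioGenotypes:
    from dataclasses import replace

    tag = frozenset([caller])
    return TrioGenotypes(
        contig=rec.contig,
        pos=rec.pos,
        ref=rec.ref,
        alt=rec.alt,
        offspring=replace(rec.offspring, callers=tag),
        sire=replace(rec.sire, callers=tag),
        dam=replace(rec.dam, callers=tag),
    )


def make_amplicon_reference(
    guide: GuideSpec, seed: int = 0, flank: int = 80
) -> str:
    """Random-flank amplicon containing the guide's on-target site."""
    rng = np.random.default_rng([seed, 4])
    left = _BASES[rng.integers(0, 4, size=flank)].tobytes().decode("ascii")
    right = _BASES[rng.integers(0, 4, size=flank)].tobytes().decode("ascii")
    pam = []
    from .guides import IUPAC_CODES

    for ch in guide.pam_pattern:
        allowed = sorted(IUPAC_CODES[ch])
        pam.append(allowed[int(rng.integers(0, len(allowed)))])
    return left + guide.protospacer + "".join(pam) + right


def simulate_amplicon_reads(
    guide: GuideSpec,
    locus_sequence: str,
    config: SimulationConfig,
    deletion_length: int = 5,
) -> tuple[list[str], dict]:
    """Amplicon read pool with configurable edit/indel/reference mix.

    ``amplicon_edit_fraction`` of reads carry C>T at every editable
    window cytosine, ``amplicon_indel_fraction`` carry a fixed-length
    deletion at the window, and the remainder are reference; each base
    is then perturbed independently at ``sequencing_error_rate``.
    Returns the reads and the realized ground-truth fractions.
    """
    from .amplicon import window_in_amplicon

    rng = _rng(config.seed, 5)
    reference = locus_sequence.upper()
    window, targets, strand = window_in_amplicon(reference, guide)
    if not targets:
        raise ConfigurationError(
            "guide editing window contains no editable cytosine"
        )
    edited_base = "T" if strand == "+" else "A"

    n = config.amplicon_n_reads
    n_edit = round(config.amplicon_edit_fraction * n)
    n_indel = round(config.amplicon_indel_fraction * n)
    if n_edit + n_indel > n:
        raise ConfigurationError("edit and indel read counts exceed the pool")

    edited = list(reference)
    for p in targets:
        edited[p] = edited_base
    edited_read = "".join(edited)
    del_start = targets[0]
    deleted_read = reference[:del_start] + reference[del_start + deletion_length :]
    # report the left-normalized gap, matching aligner/VCF convention
    g = del_start
    while g > 0 and reference[g - 1] == reference[g + deletion_length - 1]:
        g -= 1

    templates = (
        [edited_read] * n_edit
        + [deleted_read] * n_indel
        + [reference] * (n - n_edit - n_indel)
    )
    order = rng.permutation(n)
    reads = []
    err = config.sequencing_error_rate
    for i in order:
        read = templates[int(i)]
        if err > 0:
            arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(len(arr)) < err)[0]
            for h in hits:
                cur = chr(arr[h])
                arr[h] = ord("ACGT".replace(cur, "")[int(rng.integers(0, 3))])
            read = arr.tobytes().decode("ascii")
        reads.append(read)

    truth = {
        "edit_fraction": n_edit / n,
        "indel_fraction": n_indel / n,
        "reference_fraction": (n - n_edit - n_indel) / n,
        "target_positions": list(targets),
        "per_position_edit_fraction": {str(p): n_edit / n for p in targets},
        "deletion_interval": [g, g + deletion_length],
        "guide_strand": strand,
    }
    return reads, truth


def simulate_founder_svs(
    genome: ReferenceGenome,
    seed: int,
    animals: tuple[str, ...] = ("founder28", "founder34", "founder42"),
    n_denovo_per_animal: tuple[int, ...] = (4, 3, 3),
    n_common: int = 2,
    n_low_support: int = 2,
    n_scaffold: int = 1,
    mean_depth: float = 37.0,
) -> tuple[dict[str, list[StructuralVariant]], dict[str, list[tuple]]]:
    """Per-founder SV tables exercising every de novo SV filter rule.

    Each animal receives true de novo SVs (chromosome contigs, strong
    support, not shared), plus confounders: SVs shared between founder
    pairs, SVs with sub-50% supporting-read fraction, and SVs on
    scaffolds.  Returns the tables and per-animal expected survivors.
    """
    rng = np.random.default_rng([seed, 6])
    chroms = [c for c in genome.contigs if not genome.is_scaffold(c)]
    scaffolds = [c for c in genome.contigs if genome.is_scaffold(c)]
    if not chroms:
        raise CapacityError("no chromosome-class contigs for SV simulation")
    types = ["DEL", "INS", "INV"]

    placed: list[tuple[str, int, int]] = []

    def random_sv(animal: str, contig: str, support_frac: float) -> StructuralVariant:
        # avoid accidental overlap between independently placed events so
        # the founder-commonality rule only fires on deliberate copies
        # event sizes scale with the contig so toy genomes have capacity
        hi_len = int(min(20000, max(1500, len(genome[contig]) // 30)))
        for _ in range(200):
            length = int(rng.integers(hi_len // 3, hi_len))
            max_start = max(1, len(genome[contig]) - length - 1)
            start = int(rng.integers(0, max_start))
            if any(
                c == contig and start < e and start + length > s
                for c, s, e in placed
            ):
                continue
            break
        else:
            raise CapacityError("could not place a non-overlapping SV")
        placed.append((contig, start, start + length))
        depth = max(1, int(rng.poisson(mean_depth)))
        return StructuralVariant(
            contig=contig,
            start=start,
            end=start + length,
            sv_type=types[int(rng.integers(0, len(types)))],
            supporting_reads=max(0, int(round(support_frac * depth))),
            local_depth=depth,
            sample_id=animal,
        )

    tables: dict[str, list[StructuralVariant]] = {a: [] for a in animals}
    expected: dict[str, list[tuple]] = {a: [] for a in animals}

    for animal, n_dn in zip(animals, n_denovo_per_animal):
        for _ in range(n_dn):
            sv = random_sv(animal, chroms[int(rng.integers(0, len(chroms)))], 0.8)
            tables[animal].append(sv)
            expected[animal].append((sv.contig, sv.start, sv.end, sv.sv_type))
        for _ in range(n_low_support):
            tables[animal].append(
                random_sv(animal, chroms[int(rng.integers(0, len(chroms)))], 0.25)
            )
        if scaffolds:
            for _ in range(n_scaffold):
                tables[animal].append(
                    random_sv(animal, scaffolds[int(rng.integers(0, len(scaffolds)))], 0.8)
                )

    # founder-shared SVs: identical event in a random pair of animals
    for _ in range(n_common):
        sv = random_sv(animals[0], chroms[int(rng.integers(0, len(chroms)))], 0.8)
        pair = rng.choice(len(animals), size=2, replace=False)
        for ai in pair:
            animal = animals[int(ai)]
            tables[animal].append(
                StructuralVariant(
                    contig=sv.contig,
                    start=sv.start,
                    end=sv.end,
                    sv_type=sv.sv_type,
                    supporting_reads=sv.supporting_reads,
                    local_depth=sv.local_depth,
                    sample_id=animal,
                )
            )
    return tables, expected


def write_fastq(reads: list[str], path: str | Path, prefix: str = "read") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{read}\n+\n{'I' * len(read)}\n")
    return path


def read_fastq(path: str | Path) -> list[str]:
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                reads.append(line.strip())
    return reads


def write_simulation(
    outdir: str | Path,
    config: SimulationConfig,
    guide: GuideSpec = DEFAULT_GUIDE,
    n_planted: int = 5,
    mismatches_per_site: list[int] | None = None,
) -> dict[str, Path]:
    """Run the full simulation and write every pipeline input to disk.

    Emits the reference FASTA (+ .fai), two trio VCFs (one per
    emulated caller), two sites-only known-SNP database VCFs, founder
    SV tables, an amplicon FASTQ and the ground-truth JSON sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mismatches = mismatches_per_site or [1, 2, 2, 3, 3][:n_planted]

    genome = simulate_genome(config)
    genome, _planted = plant_offtarget_homologs(
        genome, guide, len(mismatches), mismatches, seed=config.seed
    )
    trio_a, trio_b, truth = simulate_trio_calls(genome, config, guide=guide)

    paths: dict[str, Path] = {}
    paths["genome"] = genome.to_fasta(outdir / "genome.fa")
    paths["trio_callerA"] = write_trio_vcf(trio_a, genome, outdir / "trio_callerA.vcf")
    paths["trio_callerB"] = write_trio_vcf(trio_b, genome, outdir / "trio_callerB.vcf")

    db_keys = sorted(truth.keys("db_known_sites"))
    half = len(db_keys) // 2
    paths["db_public"] = write_sites_vcf(db_keys[:half], genome, outdir / "db_public.vcf")
    paths["db_cohort"] = write_sites_vcf(db_keys[half:], genome, outdir / "db_cohort.vcf")

    sv_tables, _sv_truth = simulate_founder_svs(genome, seed=config.seed)
    for animal, svs in sv_tables.items():
        paths[f"sv_{animal}"] = write_sv_table(svs, outdir / f"sv_{animal}.tsv")

    amplicon_ref = make_amplicon_reference(guide, seed=config.seed)
    reads, amp_truth = simulate_amplicon_reads(guide, amplicon_ref, config)
    truth.true_amplicon_fractions = amp_truth
    with open(outdir / "amplicon_reference.fa", "w") as fh:
        fh.write(">amplicon\n" + amplicon_ref + "\n")
    paths["amplicon_reference"] = outdir / "amplicon_reference.fa"
    paths["amplicon_reads"] = write_fastq(reads, outdir / "amplicon_reads.fastq")
    paths["ground_truth"] = truth.to_json(outdir / "ground_truth.json")
    return paths
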