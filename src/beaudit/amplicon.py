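"""Amplicon deep-sequencing quantification of editing outcomes.

Reads from a targeted PCR amplicon are aligned to the amplicon
reference with a deliberately simple model suited to short, fixed
amplicons: 15-bp exact anchors at both ends, then either ungapped
substitution-only placement (equal-length reads) or a single leftmost,
minimum-mismatch gap (indel reads).  From the per-position base-count
matrix we derive substitution/indel frequencies, editing-window C>T
rates, mosaic genotype summaries and an off-target panel report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .guides import GuideSpec, revcomp

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

ANCHOR_LENGTH = 15
#: maximum non-gap mismatch fraction before a read is discarded
MAX_MISMATCH_FRACTION = 0.2


class AmpliconError(ValueError):
    pass


@dataclass
class AmpliconProfile:
    """Per-position base counts plus indel counts over one amplicon.

    ``base_counts`` is a 4 x L matrix (rows A, C, G, T); deletion
    counts are per reference position, insertion counts per gap
    between positions.  ``window_positions`` are the 0-based amplicon
    coordinates of the guide's editing window; ``target_positions``
    the subset that carries an editable base (C on the guide strand).
    ``guide_strand`` is '+' when the protospacer matches the amplicon
    forward strand, '-' when it matches the reverse complement (the
    editable base then reads G>A in amplicon coordinates).
    """

    reference: str
    base_counts: np.ndarray
    deletion_counts: np.ndarray
    insertion_counts: np.ndarray
    n_reads_total: int
    n_aligned: int
    n_discarded: int
    window_positions: tuple[int, ...]
    target_positions: tuple[int, ...]
    guide_strand: str
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.reference)

    def coverage(self) -> np.ndarray:
        """Aligned reads covering each position (bases + deletions)."""
        return self.base_counts.sum(axis=0) + self.deletion_counts

    def substitution_frequency(self, pos: int, alt: str) -> float:
        """Frequency of *alt* at 0-based position *pos* among covered reads."""
        cov = self.base_counts[:, pos].sum() + self.deletion_counts[pos]
        if cov == 0:
            return 0.0
        return self.base_counts[_BASE_INDEX[alt], pos] / cov

    def deletion_frequency(self, pos: int) -> float:
        cov = self.base_counts[:, pos].sum() + self.deletion_counts[pos]
        if cov == 0:
            return 0.0
        return self.deletion_counts[pos] / cov

    def target_conversion_counts(self) -> tuple[int, int]:
        """(converted reads, covered reads) summed over target positions.

        Conversion is C>T on the guide strand, i.e. G>A in amplicon
        coordinates when the guide matches the reverse strand.
        """
        edited_base = "T" if self.guide_strand == "+" else "A"
        k = n = 0
        for pos in self.target_positions:
            cov = self.base_counts[:, pos].sum()  # deletions not informative
            k += int(self.base_counts[_BASE_INDEX[edited_base], pos])
            n += int(cov)
        return k, n

    def target_conversion_frequency(self) -> float:
        k, n = self.target_conversion_counts()
        return k / n if n else 0.0

    def background_error_rate(self) -> float:
        """Mean per-position non-reference frequency outside the window.

        Anchor positions are excluded (exact anchors force them to the
        reference) so the estimate reflects true sequencing error.
        """
        rates = []
        excluded = set(self.window_positions)
        excluded.update(range(ANCHOR_LENGTH))
        excluded.update(range(self.length - ANCHOR_LENGTH, self.length))
        for pos in range(self.length):
            if pos in excluded:
                continue
            cov = self.base_counts[:, pos].sum()
            if cov == 0:
                continue
            ref_i = _BASE_INDEX.get(self.reference[pos])
            if ref_i is None:
                continue
            rates.append(1.0 - self.base_counts[ref_i, pos] / cov)
        return float(np.mean(rates)) if rates else 0.0

    def frequency_table(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        cov = self.coverage().astype(float)
        cov[cov == 0] = np.nan
        data = {"pos": np.arange(self.length), "ref": list(self.reference)}
        for b in _BASES:
            data[b] = self.base_counts[_BASE_INDEX[b]] / cov
        data["del"] = self.deletion_counts / cov
        data["in_window"] = [p in set(self.window_positions) for p in range(self.length)]
        return pd.DataFrame(data).fillna(0.0)


@dataclass(frozen=True)
class GenotypeCallSummary:
    """Read-class fractions at the target locus."""

    fraction_reference: float
    fraction_precise_edit: float
    fraction_indel: float
    fraction_other: float
    mosaic_flag: bool
    n_reads: int
    low_coverage: bool = False

    def fractions(self) -> dict[str, float]:
        return {
            "reference": self.fraction_reference,
            "precise_edit": self.fraction_precise_edit,
            "indel": self.fraction_indel,
            "other": self.fraction_other,
        }


def locate_protospacer(reference: str, guide: GuideSpec) -> tuple[int, str]:
    """Find the protospacer in the amplicon; returns (0-based start, strand).

    The start is always in forward amplicon coordinates; for a
    minus-strand hit it is the start of the reverse-complemented
    protospacer's footprint.
    """
    reference = reference.upper()
    i = reference.find(guide.protospacer)
    if i >= 0:
        return i, "+"
    rc = revcomp(guide.protospacer)
    i = reference.find(rc)
    if i >= 0:
        return i, "-"
    raise AmpliconError("protospacer not found in amplicon reference (either strand)")


def window_in_amplicon(reference: str, guide: GuideSpec) -> tuple[tuple[int, ...], tuple[int, ...], str]:
    """Map editing-window and editable-base positions to amplicon coordinates."""
    start, strand = locate_protospacer(reference, guide)
    L = guide.length
    window = []
    targets = []
    for idx in guide.window_indices():  # 0-based protospacer index, PAM-distal end
        if strand == "+":
            pos = start + idx
        else:
            pos = start + (L - 1 - idx)
        window.append(pos)
        if guide.protospacer[idx] == "C":
            targets.append(pos)
    return tuple(sorted(window)), tuple(sorted(targets)), strand


def _align_single_gap(read: str, ref: str) -> tuple[int, int, str, np.ndarray] | None:
    """Place one gap, leftmost among minimum-mismatch placements.

    Returns (gap_pos_in_ref, gap_len, kind, mismatch-mask over read
    positions in ref coordinates is handled by the caller); None when
    the read cannot be placed.
    """
    diff = len(ref) - len(read)
    if diff == 0:
        return None
    if diff > 0:
        kind, short, long_, d = "del", read, ref, diff
    else:
        kind, short, long_, d = "ins", ref, read, -diff
    s = np.frombuffer(short.encode(), dtype=np.uint8)
    l = np.frombuffer(long_.encode(), dtype=np.uint8)
    n = len(s)
    # pre[g]: mismatches of short[:g] vs long[:g]; suf[g]: short[g:] vs long[g+d:]
    head = (s != l[:n]).astype(np.int32)
    tail = (s != l[d : d + n]).astype(np.int32)
    pre = np.concatenate([[0], np.cumsum(head)])
    suf = np.concatenate([np.cumsum(tail[::-1])[::-1], [0]])
    total = pre + suf
    g = int(np.argmin(total))  # argmin returns the leftmost minimum
    return g, d, kind, total[g]


@dataclass
class _AlignedRead:
    gap_pos: int  # in ref coordinates; -1 when ungapped
    gap_len: int
    kind: str  # 'match', 'del', 'ins'
    ref_bases: dict[int, str]  # ref position -> read base


def _align_read(read: str, ref: str) -> _AlignedRead | None:
    read = read.upper()
    if abs(len(read) - len(ref)) >= 50:
        return None
    if len(read) < 2 * ANCHOR_LENGTH:
        return None
    if read[:ANCHOR_LENGTH] != ref[:ANCHOR_LENGTH]:
        return None
    if read[-ANCHOR_LENGTH:] != ref[-ANCHOR_LENGTH:]:
        return None
    if len(read) == len(ref):
        mism = sum(a != b for a, b in zip(read, ref))
        if mism > MAX_MISMATCH_FRACTION * len(ref):
            return None
        return _AlignedRead(
            gap_pos=-1,
            gap_len=0,
            kind="match",
            ref_bases={i: read[i] for i in range(len(read))},
        )
    placed = _align_single_gap(read, ref)
    if placed is None:
        return None
    g, d, kind, mism = placed
    if mism > MAX_MISMATCH_FRACTION * len(ref):
        return None
    bases: dict[int, str] = {}
    if kind == "del":
        for i in range(g):
            bases[i] = read[i]
        for i in range(g, len(read)):
            bases[i + d] = read[i]
    else:  # insertion relative to reference
        for i in range(g):
            bases[i] = read[i]
        for i in range(g, len(ref)):
            bases[i] = read[i + d]
    return _AlignedRead(gap_pos=g, gap_len=d, kind=kind, ref_bases=bases)


def _classify(
    aln: _AlignedRead,
    reference: str,
    window_positions: tuple[int, ...],
    target_positions: tuple[int, ...],
    guide_strand: str,
) -> str:
    if aln.kind != "match":
        return "indel"
    edited_base = "T" if guide_strand == "+" else "A"
    window_matches_ref = all(
        aln.ref_bases.get(p) == reference[p] for p in window_positions
    )
    if window_matches_ref:
        return "reference"
    precise = target_positions and all(
        aln.ref_bases.get(p) == edited_base for p in target_positions
    ) and all(
        aln.ref_bases.get(p) == reference[p]
        for p in window_positions
        if p not in target_positions
    )
    return "precise_edit" if precise else "other"


def profile_amplicon(
    reads: list[str], reference_amplicon: str, guide: GuideSpec
) -> AmpliconProfile:
    """Align reads to the amplicon and accumulate count matrices."""
    if not reads:
        raise AmpliconError("empty read pool")
    reference = reference_amplicon.upper()
    L = len(reference)
    window, targets, strand = window_in_amplicon(reference, guide)

    base_counts = np.zeros((4, L), dtype=np.int64)
    del_counts = np.zeros(L, dtype=np.int64)
    ins_counts = np.zeros(L + 1, dtype=np.int64)
    classes = {"reference": 0, "precise_edit": 0, "indel": 0, "other": 0}
    n_discarded = 0

    for read in reads:
        aln = _align_read(read, reference)
        if aln is None:
            n_discarded += 1
            continue
        for pos, base in aln.ref_bases.items():
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                base_counts[idx, pos] += 1
        if aln.kind == "del":
            del_counts[aln.gap_pos : aln.gap_pos + aln.gap_len] += 1
        elif aln.kind == "ins":
            ins_counts[aln.gap_pos] += 1
        classes[_classify(aln, reference, window, targets, strand)] += 1

    return AmpliconProfile(
        reference=reference,
        base_counts=base_counts,
        deletion_counts=del_counts,
        insertion_counts=ins_counts,
        n_reads_total=len(reads),
        n_aligned=len(reads) - n_discarded,
        n_discarded=n_discarded,
        window_positions=window,
        target_positions=targets,
        guide_strand=strand,
        class_counts=classes,
    )


def call_genotype_summary(
    profile: AmpliconProfile,
    min_reads: int = 1000,
    mosaic_threshold: float = 0.10,
) -> GenotypeCallSummary:
    """Classify read fractions and flag mosaicism.

    Mosaicism is flagged when at least two non-reference classes each
    exceed *mosaic_threshold* — e.g. a precise point edit coexisting
    with a deletion allele.
    """
    n = profile.n_aligned
    low = n < min_reads
    if low:
        warnings.warn(
            f"only {n} aligned reads (< {min_reads}); genotype summary is "
            "low-coverage",
            stacklevel=2,
        )
    if n == 0:
        return GenotypeCallSummary(0.0, 0.0, 0.0, 0.0, False, 0, low)
    frac = {k: v / n for k, v in profile.class_counts.items()}
    non_ref = [frac["precise_edit"], frac["indel"], frac["other"]]
    mosaic = sum(f > mosaic_threshold for f in non_ref) >= 2
    return GenotypeCallSummary(
        fraction_reference=frac["reference"],
        fraction_precise_edit=frac["precise_edit"],
        fraction_indel=frac["indel"],
        fraction_other=frac["other"],
        mosaic_flag=mosaic,
        n_reads=n,
        low_coverage=low,
    )


def _binomial_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval."""
    if n == 0:
        return (0.0, 1.0)
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return (float(lo), float(hi))


def offtarget_panel_frequencies(
    pools: dict[str, list[str]],
    references: dict[str, str],
    guide: GuideSpec,
    min_edit_frequency: float = 0.005,
) -> "pd.DataFrame":  # noqa: F821
    """Per-site editing-window conversion frequencies for a site panel.

    For each predicted off-target amplicon, reports the C>T (or G>A on
    minus-oriented sites) frequency over editable window positions with
    a 95% Clopper-Pearson interval, the background per-base error
    estimated from non-window positions, and an ``edited`` flag set
    when the frequency exceeds background by more than
    ``max(min_edit_frequency, 3 x background)``.
    """
    import pandas as pd

    rows = []
    for name in pools:
        profile = profile_amplicon(pools[name], references[name], guide)
        k, n = profile.target_conversion_counts()
        freq = k / n if n else 0.0
        lo, hi = _binomial_ci(k, n)
        background = profile.background_error_rate()
        threshold = max(min_edit_frequency, 3 * background)
        rows.append(
            {
                "site": name,
                "converted_reads": k,
                "covered_reads": n,
                "frequency": freq,
                "ci_low": lo,
                "ci_high": hi,
                "background_error": background,
                "edited": freq - background > threshold,
            }
        )
    return pd.DataFrame(rows)
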