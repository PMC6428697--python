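# Methods

`beaudit` implements the downstream genetic audit of a cytosine
base-editing animal experiment: given caller output (VCF), known-SNP
databases, structural-variant tables and amplicon reads, it asks
whether an edited offspring carries (a) unintended edits at
guide-homologous loci, (b) an elevated burden of de novo mutations,
and (c) what mixture of alleles the targeted locus itself carries.
The package does not align reads or call variants — BWA, GATK,
SAMtools and BreakDancer (or their equivalents) are upstream
producers whose output formats it consumes.

## Off-target site search

A candidate off-target site of a guide with protospacer $P$ (length
$L$, default 20) and PAM pattern $M$ (IUPAC, default `NGG`) is any
genomic window of length $L+|M|$, on either strand, whose PAM
substring matches $M$ exactly and whose protospacer substring differs
from $P$ in at most $k$ ungapped substitutions.  Conventions:

- mismatches are counted over the protospacer only; a window whose
  PAM does not match is rejected outright regardless of protospacer
  identity — this matches the documented behaviour of the standard
  site-enumeration tools (SeqMap-class searches for small $k$,
  Cas-OFFinder-class for $k \le 5$);
- a window containing an ambiguous base (`N`) is rejected entirely;
  pattern `N` matches A/C/G/T but never a genomic `N`, so assembly
  gaps cannot produce spurious sites;
- mismatch positions are reported 1-based from the PAM-distal end of
  the protospacer;
- DNA/RNA bulges (gapped alignments) are out of scope;
- coordinates are 0-based half-open internally and in BED output,
  1-based only in VCF interchange.

The implementation vectorises the scan with a PAM pre-screen (a
per-position boolean lookup over encoded bases selects candidate
windows, typically ~1/16 of positions for `NGG`) followed by batch
mismatch counting on the survivors.  A deliberately naive
character-by-character sliding-window scorer ships in the test suite
as the semantics ground truth; the two are asserted set-equal on all
fields over randomized planted genomes for $k \in \{0,1,3,5\}$.

Two search depths mirror common practice: $k=3$ to choose an amplicon
validation panel, $k=5$ for the genome-wide audit intervals.
Predicted sites are merged into strand-collapsed intervals (optionally
flanked) before variant intersection.

## Off-target mutation cascade

Offspring SNVs pass through five ordered filters, each recorded in a
funnel of (stage, n_in, n_out):

1. **caller intersection** — keep calls reported by both callers at
   the same (contig, pos, ref, alt).  On consensus, caller A's
   genotype/depth/PL are authoritative; the callers simply disagree
   too rarely and too arbitrarily for a principled merge, and the
   choice is logged in the record's provenance.
2. **known-database exclusion** — drop calls whose full key appears
   in any known-SNP database.  Matching is allele-aware, not
   position-only: a novel allele at a known polymorphic site is a
   legitimate candidate and would be masked by positional matching.
3. **parental-inheritance exclusion** — drop calls whose alt allele
   is carried by either parent in either caller's *raw* set
   (pre-intersection), so caller dropout in a parent cannot rescue an
   inherited variant.
4. **C/G-substitution selection** — keep SNVs with reference base C
   or G.  Cytosine deamination converts C:G pairs; read out on the
   reference strand that is C>N or its antisense G>N.  The broader
   rule (any alt) is the default; `strict_bisulfite_signature`
   narrows it to the canonical C>T / G>A products.  The selection is
   applied *before* interval intersection, preserving the
   conventional ordering even though the two stages commute.
5. **off-target interval intersection** — keep calls whose position
   falls inside a merged predicted off-target interval.

Multiallelic records are decomposed to biallelic on ingest so the
site keys above are well defined (naive decomposition: other alt
alleles collapse to reference; the PL vector is subset to the
(0/0, 0/alt, alt/alt) entries).

## De novo mutation identification

De novo candidates are offspring calls, present in both callers and
absent from all databases, at which the offspring carries an alt
allele found in neither parent's genotype.  Sites with a missing
parental genotype cannot be certified de novo and are excluded with a
separate count.  Candidates are then filtered on evidence:

- depth of every trio member ≥ `min_depth_each_member` (default 10);
- offspring PL for every genotype other than the call ≥
  `min_pl_second_best_offspring` (default 20);
- each parent's PL for every alt-carrying genotype ≥
  `min_pl_homref_parents` (default 20).

The defaults are conventional trio-sequencing values; the source
studies this procedure descends from do not print their exact
cutoffs, so all three are configuration-overridable and logged.

Manual curation of suspicious candidates is intentionally not
reproduced.  Instead the pipeline attaches explicit review flags —
`clustered` when another candidate lies within 5 bp, `homopolymer`
when the site falls in a reference homopolymer run of ≥ 6 bp — and
never silently drops a flagged record.  Auditable flags replace an
unreproducible step at the cost of a slightly longer output list.

### Structural variants

BreakDancer-style events per founder are filtered by three rules:
(a) events sharing type and ≥ 50% reciprocal overlap with an event in
any other founder are removed from every carrier (founder-shared
events are almost surely inherited or artefactual); (b) events whose
supporting-read count is less than half the local depth are removed —
"depth below 50%" is interpreted as supporting-read fraction, the
reading that is computable from a BreakDancer-like table alone, and
the threshold is switchable; (c) events on scaffold-class contigs are
removed.  No overlap rule is inherited from upstream tools, so the
50% reciprocal-overlap convention of population SV studies is used.

### Kinship verification

Pedigree integrity is checked with the KING-robust estimator over
shared biallelic SNP genotypes:

$$\varphi = \frac{N_{Het,Het} - 2\,N_{AA,aa}}{N_{Het}(i) + N_{Het}(j)}$$

Expected values: ~0.25 for parent–offspring, ~0 for unrelated
founders, exactly 0.5 for a sample against itself (no opposite
homozygotes, every het shared).  A zero denominator is reported as
missing rather than guessed.

## Amplicon genotyping

Reads from a targeted amplicon are aligned with a model chosen for
short fixed amplicons rather than generality: 15-bp exact anchors at
both ends, then either ungapped placement (equal-length reads,
substitutions only) or a single gap placed leftmost among
minimum-mismatch placements (matching VCF indel normalization).
Reads failing the anchors, differing by ≥ 50 bp, or exceeding 20%
non-gap mismatches are counted as discarded; total classified +
discarded always equals input reads.

Aligned reads are classified at the editing window (protospacer
positions 4–8 from the PAM-distal end by default, the canonical
cytosine-deaminase window): `reference` (window matches reference),
`precise_edit` (every editable window cytosine read as T — G>A in
amplicon coordinates for minus-oriented sites — and no other window
change), `indel` (any gap), `other` (any other window change).  The
genotype summary reports the four fractions (which sum to 1 over
aligned reads) and flags mosaicism when at least two non-reference
classes each exceed 0.10 — e.g. a point edit coexisting with a
deletion allele.  Below 1000 aligned reads a low-coverage warning is
attached but the summary is still produced.

For an off-target amplicon panel, per-site conversion frequencies
over editable window positions are reported with exact
Clopper–Pearson 95% intervals.  Background error is estimated from
non-window, non-anchor positions of the same profile; a site is
flagged `edited` when frequency minus background exceeds
`max(0.5%, 3 × background)`.  The 0.5% floor reflects the resolution
practically achievable without unique molecular identifiers; both
constants are parameters.

## Mutation rate

With $n$ de novo mutations over a callable haploid genome of $C$ bp
in one generation, the per-bp per-generation rate is
$\hat\mu = n / (2C)$ — the factor 2 is the diploid transmission
denominator, stated prominently because published cohort rates mix
conventions.  An exact Poisson 95% interval on $n$ is propagated to
the rate.  $C$ defaults to total non-N genome length; a callable-
regions BED can override it.  External cohort rates for comparison
tables are always user-supplied configuration, never built in.

## Synthetic data

The simulator generates every input with known ground truth, under
study-like conditions: mean sequencing depth 37× (typical trio WGS
coverage), 20 de novo SNPs and 10 de novo indels per offspring (the
magnitude observed in edited-animal trios), indel lengths 1–23 bp
(the range seen at edited loci), zero spiked off-target edits by
default (the expected outcome for a specific guide), and noiseless
genotypes by default so downstream output can be compared with truth
exactly.  Design choices:

- **Two callers by thinning.**  Rather than emulating two error
  models, one master call set is thinned: each record is dropped from
  exactly one caller with probability `caller_discordance_rate`.
  This isolates the intersection logic, which is what the cascade
  defines, and makes the recoverable truth (the both-caller subset)
  exact.
- **Segregating sites.**  Inherited and database-known sites draw an
  allele frequency from U(0.2, 0.8), parents from Hardy–Weinberg, and
  the offspring by Mendelian transmission; sites where no member
  carries the alt produce no record, as a variant-only caller would
  behave.  No conditioning is applied, which keeps the KING
  estimator exactly unbiased for both parent–offspring and founder
  pairs.
- **Placement.**  Spiked categories never share a position (minimum
  spacing 30 bp, beyond the longest indel), and all non-off-target
  variants are placed outside the guide's predicted off-target
  intervals, so the default cascade output is empty by construction
  of the truth rather than by luck.
- **PL synthesis.**  The called genotype gets PL 0; all others get
  `min(255, 40 + 3·depth)` — callers do not publish a PL generative
  model, and the pipeline only thresholds PLs, so any monotone
  depth-scaled value exercises the filters.
- **Sequencing error** is i.i.d. per base with no quality model — the
  simplest model sufficient to test frequency estimation; amplicon
  read counts per class are deterministic roundings of the requested
  fractions so that zero-noise settings are exact.

What the simulator does *not* emulate — alignment artefacts,
mapping-quality structure, indel realignment errors, batch effects,
real linkage disequilibrium — bounds what passing tests show: they
validate the *logic* of the filters and estimators, not robustness
to upstream miscalling.  Determinism is a contract: every generator
is a pure function of (config, seed), and identical configurations
yield byte-identical files.

## Problem sizes and numerical choices

The validation suite runs the search oracle on twenty 50–100 kb
two-contig genomes with planted homologs at 0–5 mismatches; trio
scenarios use 200–300 kb genomes with ~400 segregating sites; rate
calibration uses fifty replicate 10-Mb trios at a true rate of 1e-8
(about 10 expected events in total, so the mean estimate is compared
at 2 standard errors); amplicon pools use 10,000 reads, the scale at
which 3 binomial standard errors resolve a 5% edit fraction.  These
sizes were chosen as the smallest at which each property is
statistically meaningful.

Tie-breaks and degenerate inputs: interval merging treats bookended
intervals as one; the funnel refuses non-monotone or discontinuous
stage counts; self-kinship with zero heterozygous sites is missing,
not 0.5; a single-founder SV table skips the commonality rule with a
warning rather than failing.

## Known limitations

- The search is ungapped; guides whose off-target risk is dominated
  by bulge sites need a dedicated tool.
- Panel background-error estimation assumes errors are position-
  homogeneous outside the window; context-dependent error (e.g.
  8-oxo-G damage) would bias the `edited` flag at low frequencies.
- The amplicon aligner handles one indel per read; complex alleles
  (indel + distant substitution cluster) land in `other` or
  discarded.
- Caller emulation by thinning cannot express caller-specific
  systematic errors; conclusions about real GATK/SAMtools discordance
  structure are out of reach by design.
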