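# Methods

## The procedure

`targetasm` interrogates a large short-read data set for the presence of
specific sequence variants by *targeted* de novo assembly. Instead of
aligning or assembling the whole data set, it restricts the sequence space
to that of small user-supplied target sequences (typically 38–150 nt, one
per allele or event of interest) and asks whether reads from the data set
co-assemble onto each target.

The pipeline has four stages:

1. **Word indexing.** Every k-length word (default k = 15) of each target's
   plus and minus strand is stored in a hash table mapping word →
   (target, strand, offset). For a target of length L this yields
   2·(L − k + 1) entries; duplicate words from internal repeats all keep
   their hits. k = 15 balances speed against specificity: with 4¹⁵ ≈ 10⁹
   possible words, a random 36-nt read has a ~10⁻⁷ chance of a spurious
   prefix hit against a 51-nt target. Low-complexity or very long targets
   draw in more reads and degrade that specificity; word sizes below 11
   trigger a warning.

2. **Prefix-anchored recruitment.** The read stream is traversed exactly
   once; a read is retained iff its *first* k bases exactly match an indexed
   word. Opposite-strand reads are captured by the minus-strand words, so
   reads are never reverse-complemented during the scan. Anchoring to the
   read's literal prefix (rather than any internal k-mer) is deliberate:
   it is what makes the flank-extension bound of read_length − m per side
   exact (see below). Memory scales with the recruited set and the index,
   not with the data set, so arbitrarily large read sets can be streamed.

3. **Placement under perfect agreement.** Each recruited read is placed on
   the target's coordinate axis (position 0 = first target base; negative =
   left flank). A '+' hit at offset i anchors the read's prefix at i; a '−'
   hit reverse-complements the read so that its last k bases occupy
   [i, i+k), i.e. start = i + k − read_length. A placement is accepted only
   if the read overlaps the target interval by at least m bases (default
   m = 15) *and* matches the target at every in-target position it covers.
   A single mismatching base anywhere in the in-target overlap excludes the
   read entirely — assembly success is therefore itself the evidence that
   the interrogated allele is present. When a read has several acceptable
   placements on one target (internal repeats), the largest in-target
   overlap wins, ties broken by the smallest start; this rule is a package
   decision, as is treating placements on different targets independently.

4. **Consensus and bidirectional extension.** Per-position {A,C,G,T}
   tallies accumulate over the target axis, flanks included. Inside the
   target the consensus is the target verbatim (guaranteed by perfect
   agreement). Outside it the consensus grows one position at a time,
   leftward from −1 and rightward from L: a flank position is appended iff
   its depth is ≥ o (default 2) and the most represented base accounts for
   at least a fraction r (default 0.7) of the depth. The first failing
   position terminates that direction permanently — a failed position is
   never revisited, so extension is single-pass and deterministic under
   any permutation of the input reads.

### Extension arithmetic

Because recruitment is prefix-anchored, a placed read can protrude at most
read_length − m bases beyond the target on either side. With 33-nt reads
and m = 15 a target can gain at most 18 bp per flank; with 150-nt reads a
150-nt target can grow to 150 + 2·135 = 420 bp, of which 270 bp are
previously uncharacterized sequence. The acceptance script reproduces both
numbers exactly on dense synthetic tilings.

For the flank *tip* position to be reported it must meet the o = 2 depth
floor, yet only a single distinct placement (the read with exactly m bases
in-target) covers it. The dense-tiling fixtures therefore emit two reads
per (start, strand) — the regime the maximum-extension arithmetic assumes;
with a single read per start position the extension is read_length − m − 1.
This follows from the extension rule alone and was fixed before any
experiment was run.

## Parameters

| flag | meaning | default | notes |
|------|---------|---------|-------|
| -k | word size (nt) | 15 | < 11 warns: low specificity |
| -m | minimum in-target overlap (nt) | 15 | bounds flank growth at read_len − m; must be ≥ k |
| -o | minimum extension depth (reads) | 2 | flank positions only |
| -r | minimum top-base fraction | 0.7 | count(top)/depth ≥ r; ratio exactly r accepts |
| -c | minimum reported in-target depth | 1 | report trimming, see below |

Two wordings in the family of majority-rule extenders are ambiguous and are
fixed here as follows. The ratio is the top base's share of total depth
(count(top)/depth ≥ r), not top/second — the latter is degenerate (always
satisfied whenever a strict majority exists). At a tie for top base,
extension terminates whenever r > 0.5 (a tie cannot reach the ratio); for
permissive r ≤ 0.5 the alphabetically first tying base is chosen.

`-c` controls *reporting*, not assembly: the contig keeps the longest
contiguous in-target run whose depth is ≥ c (leftmost on ties), and a flank
is reported only when the kept run reaches that side of the target. With
the default c = 1 this only trims in-target positions covered by no read.
Interior low-depth gaps at c > 1 cannot split a target into multiple
contigs; one contig per target is an invariant.

Reads' N bases never match a word, never satisfy in-target agreement, and
are excluded from flank tallies; they still occupy the read's span for
spanning-read counts.

## Target design

* **SNV pairs** — two targets (default 51 nt) identical except at their
  center base, one per allele. Centering the base under scrutiny maximizes
  the number of recruiting words overlapping it; contexts shorter than
  2k + 1 warn because fewer than k words then cover the focal base.
* **Fusion probes** — four targets sharing a known prefix (≥ k) and
  differing only in an ambiguous final base. Exactly the probe matching
  the unknown molecule recruits junction-spanning reads and extends past
  its end; the right flank of its contig *is* the discovered partner
  sequence.
* **Junction/breakpoint targets** — two arms concatenated across an event
  (fusion breakpoint, deletion junction), with the junction offset recorded
  in metadata. Reads with ≥ 1 base strictly on each side of the junction
  are chimaera evidence by construction.
* Batch design from a reference FASTA plus a minimal VCF (CHROM, POS, REF,
  ALT) is supported; indel targets place the first altered base at the
  center.

## Evidence reporting

A read *spans* a focal position if it covers it at all; it spans
*interiorly* if the position lies ≥ 5 bases (configurable) from both read
ends, since base calls near read ends are least reliable. Presence/absence
calls count interior spanning reads against a threshold of 1 by default.
The alternative literal reading of the edge rule (counting only reads with
the variant *within* 5 bases of an end) would keep exactly the unreliable
reads and is rejected. Allele pairs yield a 3-way call (ref-only /
alt-only / both / no-call); deletion events are summarized as A/B counts
(A = interior reads over the non-deleted allele target, B = over the
breakpoint target).

## Synthetic data

The generator emulates the statistical structure of the read sets the tool
is designed for: unpaired 31–76 nt reads at 5–36× depth, drawn uniformly
from both strands (minus-strand reads emitted reverse-complemented), with
independent per-base substitution errors. Allele mixtures draw each read
from the alternate allele with a configurable fraction (0.5 for a
heterozygote). A single integer seed fully determines every output.

It deliberately does **not** model platform-specific error profiles,
quality scores (the assembler ignores qualities), indel sequencing errors
(the assembler is gapless, so indel errors only reduce recruitment — this
regime is covered by testing at elevated substitution rates), paired-end
structure, or non-uniform coverage. Passing tests on this generator
therefore demonstrate the algorithm's correctness and its behaviour under
substitution noise and strandedness, not robustness to real-platform
artifacts such as homopolymer errors or coverage bias.

### Study conditions used by the test suite

Problem sizes are chosen so the whole suite runs in seconds on one core
while keeping every stage in its intended regime:

* **Extension arithmetic** — 500-nt (t1) and 1,500-nt (t2) random
  references, internal 70-nt / 150-nt targets, exhaustive error-free
  tilings (two reads per start and strand, see above) of 33-nt / 150-nt
  reads; m = 15, o = 2, r = 0.7, c = 1.
* **Heterozygote recovery** — 500-nt reference, implanted 50/50 SNV,
  31-nt reads at 20× total depth and 1% substitution error, 50 seeds,
  default 51-nt centered ref/alt targets. 31 nt is a realistic
  early-platform read length and keeps prefix-anchored recruitment across
  a 51-nt target efficient.
* **Fusion discrimination** — two independent 300-nt references fused at
  150/150, 37-nt known-prefix probe set, 36-nt reads at 30× with 1%
  error, 25 seeds.
* **Oracle equivalence** — 100 random instances of ≤ 5 targets (20–100 nt)
  and ~200 random reads plus guaranteed true positives, compared against a
  naive prefix-vs-all-words double loop.

## Numerical and degenerate-input choices

* Ratio comparisons use `count(top) + 1e-9 ≥ r·depth` so that a share of
  exactly r accepts regardless of floating-point representation.
* Targets failing validation (shorter than k, non-ACGT) are rejected at
  load with named errors; duplicate target IDs get ordinal suffixes.
* Reads are uppercased and non-ACGTN symbols mapped to N; read counts are
  conserved. FASTQ is assumed 4-line; malformed records abort with the
  file and approximate record ordinal.
* Zero recruited or zero placed reads yield no contig for that target —
  a result (absence of the variant), not an error; the CLI still exits 0.

## Known limitations

* Extension is single-round by design: the extended consensus is never fed
  back as a new target, so contigs are bounded by target_length +
  2·(read_length − m).
* Recruitment is exact-match; a single error in a read's first k bases
  loses the read, and an in-target error loses its placement. Sensitivity
  therefore degrades quickly with error rate and with adjacent variation
  not encoded in the target — by construction, since that stringency is
  what makes assembly success interpretable as allele presence.
* Paired-end information is ignored; all reads are treated as fragments.
* Repeat-rich or low-complexity targets recruit non-specifically; the
  word index warns only on small k, not on target complexity.
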