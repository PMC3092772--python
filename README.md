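# targetasm

Targeted de novo assembly of short sequencing reads for variant
re-identification.

When the question is "does this read set contain allele X / this fusion
junction / this deletion breakpoint?", aligning or assembling the whole
data set is wasteful and can actively hide the answer (non-reference reads
mis-align or drop out). `targetasm` instead mines the raw reads directly:
the user supplies small target sequences — one per allele or event of
interest — and the tool retains exactly the reads that can co-assemble
onto a target, assembles them stringently, and extends the consensus
bidirectionally into unknown flanking sequence. A successful assembly is
itself the evidence that the interrogated variant is present. Typical
users are groups validating candidate SNVs from tumour genomes, confirming
fusion transcripts or viral-integration sites in RNA-seq, or re-identifying
known polymorphisms in very large whole-genome read sets.

## Algorithm

For each target *T* of length *L*:

1. every k-mer (k = 15 by default) of *T*'s plus and minus strand is stored
   in a hash table — 2·(L − k + 1) words;
2. the read stream is scanned once and a read is retained iff its **first
   k bases** exactly match some word (opposite-strand reads are caught by
   the minus-strand words);
3. each retained read is placed on *T*'s coordinate axis by its matching
   word and accepted only if it overlaps *T* by ≥ m bases (default 15) and
   agrees with *T* at **every** in-target position it covers;
4. the consensus equals *T* inside the target and grows outward one
   position at a time, appending the most represented base while depth ≥ o
   (default 2) and count(top)/depth ≥ r (default 0.7); the first failing
   position terminates that direction.

Prefix anchoring bounds flank growth at read_length − m per side: 33-nt
reads with m = 15 extend a target by at most 18 bp per flank, and 150-nt
reads on a 150-nt target yield at most 150 + 2·(150 − 15) = 420 bp contigs
with 270 previously uncharacterized bases. See `docs/methods.md` for the
full model, parameter semantics and design decisions.

## Worked example

Simulate a 500-nt reference carrying a heterozygous SNV at position 250,
sequenced as 31-nt reads at 20× with 1% error; design a ref/alt target
pair; assemble; report.

```sh
targetasm simulate --seed 7 --length 500 --read-length 31 --depth 20 \
    --error-rate 0.01 --snv-pos 250 --out-prefix sim
# targetasm: reads_written=323 prefix=sim

targetasm design --snv ACTCAGTGTGATCTTTATGCTTGAGAAAATCAACCCTTGTCACATACATAG A T \
    --id rs_demo --out targets.fa      # 51-nt context around position 250
echo sim.reads.fq > reads.fof

targetasm assemble -f reads.fof -s targets.fa -b demo
# targetasm: reads_seen=323 reads_retained=18
# targetasm: target=rs_demo.ref contig=rs_demo.ref.contig length=68 left_ext=10 right_ext=7 reads=9
# targetasm: target=rs_demo.alt contig=rs_demo.alt.contig length=68 left_ext=10 right_ext=7 reads=11

targetasm report -f reads.fof -s targets.fa -b demo
```

Of 323 reads, 18 have a prefix matching a target word; 9 place perfectly on
the reference-allele target and 11 on the alternate. Both 51-nt targets
assemble into 68-nt contigs (10 bp of novel left flank, 7 bp right — within
the 31 − 15 = 16 bp bound), and `demo.variants.tsv` shows interior
spanning-read support for both alleles, i.e. a heterozygote:

```
# variant_id	target_id	allele	n_spanning	n_interior	detected	call
rs_demo.ref	rs_demo.ref	A	4	4	True	detected
rs_demo.alt	rs_demo.alt	T	6	3	True	detected
```

`assemble` writes four files per run: `{prefix}.contigs.fa` (consensus
sequences; headers carry length, read count and the contig's target span),
`{prefix}.readpos.tsv` (read placements), `{prefix}.coverage.tsv`
(per-position depth) and `{prefix}.pileup.tsv` (per-position base tallies
in the target coordinate frame).

The same machinery discovers unknown sequence: `targetasm design
--fusion-prefix <37 known bases>` emits four probes differing only in an
ambiguous last base; exactly the probe matching the sample extends past its
end, and its right flank is the unknown fusion partner's sequence
(`targetasm.chimaera_report` counts the junction-spanning reads).

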