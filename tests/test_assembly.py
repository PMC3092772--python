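"""Placement, coverage, consensus extension and the perfect-agreement rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetasm import (
    SimulationConfig,
    TargetRecord,
    assemble_target,
    build_coverage,
    build_index,
    extend_consensus,
    place_read,
    recruit,
    simulate_reads,
    simulate_reference,
    tile_reads,
)
from targetasm.assembly import CoverageTable, PlacedRead, _call_flank_base
from targetasm.dna import revcomp
from targetasm.sequence_io import ReadRecord

TARGET51 = "ATTGCCGGATCGGACCATTGACGTGGATCAAGGCCATCGGATTACAGGATC"


def recruit_one(seq, target):
    recruited, _ = recruit([ReadRecord("r", seq, "mem")], build_index([target]))
    assert len(recruited) == 1
    return recruited[0]


class TestPlaceRead:
    def test_plus_strand_exact_subsequence(self):
        target = TargetRecord("t", TARGET51)
        rr = recruit_one(TARGET51[10:46], target)
        placed = place_read(rr, target, m=15)
        assert (placed.strand, placed.start) == ("+", 10)
        assert placed.oriented_sequence == TARGET51[10:46]

    def test_minus_strand_coordinate_arithmetic(self):
        """Reverse-complement read of target[0:36): '-' hit at offset 21 places
        the oriented read at start 21 + 15 - 36 = 0."""
        target = TargetRecord("t", TARGET51)
        rr = recruit_one(revcomp(TARGET51[0:36]), target)
        placed = place_read(rr, target, m=15)
        assert (placed.strand, placed.start) == ("-", 0)
        assert placed.oriented_sequence == TARGET51[0:36]

    def test_minus_strand_brute_force_alignment(self):
        """Placement agrees with exhaustively sliding the oriented read."""
        target = TargetRecord("t", TARGET51)
        read = revcomp(TARGET51[5:41])
        rr = recruit_one(read, target)
        placed = place_read(rr, target, m=15)
        oriented = revcomp(read)
        matches = [
            s
            for s in range(-36, 51)
            if all(
                oriented[j - s] == TARGET51[j]
                for j in range(max(s, 0), min(s + 36, 51))
            )
            and min(s + 36, 51) - max(s, 0) >= 15
        ]
        assert placed.start in matches and placed.start == 5

    def test_in_target_mismatch_rejected(self):
        target = TargetRecord("t", TARGET51)
        # prefix matches word at offset 0, but base 20 differs from the target
        seq = TARGET51[:20] + ("A" if TARGET51[20] != "A" else "C") + TARGET51[21:36]
        rr = recruit_one(seq, target)
        assert place_read(rr, target, m=15) is None

    def test_insufficient_overlap_rejected(self):
        target = TargetRecord("t", TARGET51)
        rr = recruit_one(TARGET51[36:] + "ACGTACGTACGTACGTACGTA", target)
        assert place_read(rr, target, m=16) is None  # only 15 in-target bases

    def test_flank_mismatch_is_tolerated(self):
        """Perfect agreement applies only inside the target; flank bases are free."""
        target = TargetRecord("t", TARGET51)
        rr = recruit_one(TARGET51[36:] + "ACGTACGTACGTACGTACGTA", target)
        placed = place_read(rr, target, m=15)
        assert placed is not None and placed.start == 36


class TestCoverage:
    def test_additivity_of_identical_reads(self):
        placed = [
            PlacedRead("a", "f", "+", 3, "ACGTAC"),
            PlacedRead("b", "f", "+", 3, "ACGTAC"),
        ]
        cov = build_coverage(placed)
        for j, base in enumerate("ACGTAC"):
            assert cov.counts(3 + j) == {base: 2}

    def test_empty(self):
        assert len(build_coverage([])) == 0

    def test_recount_oracle_on_tiling(self):
        """Coverage equals a brute-force per-position recount."""
        ref = simulate_reference(SimulationConfig(seed=5, reference_length=400))
        target = TargetRecord("t", ref[120:270])
        recruited, _ = recruit(tile_reads(ref, 40), build_index([target]))
        placed = [p for p in (place_read(r, target) for r in recruited) if p]
        cov = build_coverage(placed)
        recount: dict[int, dict[str, int]] = {}
        for pr in placed:
            for j, base in enumerate(pr.oriented_sequence):
                recount.setdefault(pr.start + j, {}).setdefault(base, 0)
                recount[pr.start + j][base] += 1
        assert {p: cov.counts(p) for p in cov.positions()} == recount

    def test_n_bases_not_counted(self):
        cov = build_coverage([PlacedRead("a", "f", "+", -3, "ANG")])
        assert cov.counts(-3) == {"A": 1}
        assert cov.counts(-2) == {}
        assert cov.counts(-1) == {"G": 1}


class TestExtensionRule:
    """Majority-rule flank calls at the -o depth and -r ratio boundaries."""

    def test_accepts_above_both_thresholds(self):
        assert _call_flank_base({"A": 3, "C": 1}, o=2, r=0.7) == "A"  # ratio 0.75

    def test_depth_below_o_terminates(self):
        assert _call_flank_base({"A": 1}, o=2, r=0.7) is None

    def test_ratio_just_below_r_terminates(self):
        assert _call_flank_base({"A": 2, "C": 1}, o=2, r=0.7) is None  # 2/3 < 0.7

    def test_ratio_exactly_r_accepts(self):
        assert _call_flank_base({"A": 7, "C": 3}, o=2, r=0.7) == "A"  # 7/10 == 0.7

    def test_tie_terminates_for_majority_r(self):
        assert _call_flank_base({"A": 2, "C": 2}, o=2, r=0.7) is None

    def test_tie_breaks_alphabetically_for_permissive_r(self):
        assert _call_flank_base({"C": 2, "A": 2}, o=2, r=0.5) == "A"

    def test_first_failing_position_stops_direction(self):
        target = TargetRecord("t", "ACGTACGTACGTACGTACGT")
        cov = CoverageTable()
        for pr in [
            PlacedRead("a", "f", "+", -1, "G" + target.sequence[:19]),
            PlacedRead("b", "f", "+", -1, "G" + target.sequence[:19]),
            # depth gap at -2; deeper coverage at -3 must not be reachable
            PlacedRead("c", "f", "+", -5, "TTT"),
            PlacedRead("d", "f", "+", -5, "TTT"),
        ]:
            cov.add_read(pr)
        contig = extend_consensus(cov, target, o=2, r=0.7)
        assert contig.left_ext == 1
        assert contig.sequence.startswith("G" + target.sequence[:5])


class TestAssembleTarget:
    def test_extension_limit_33nt_reads(self):
        """33-nt reads with m=15 extend a 70-nt target by exactly 18 per side."""
        ref = simulate_reference(SimulationConfig(seed=1, reference_length=300))
        target = TargetRecord("t70", ref[120:190])
        recruited, _ = recruit(tile_reads(ref, 33), build_index([target]))
        contig = assemble_target(target, recruited, m=15)
        assert (contig.left_ext, contig.right_ext) == (18, 18)
        assert contig.sequence == ref[102:208]

    def test_150nt_reads_yield_420nt_contig(self):
        ref = simulate_reference(SimulationConfig(seed=2, reference_length=1500))
        target = TargetRecord("t150", ref[700:850])
        recruited, _ = recruit(tile_reads(ref, 150), build_index([target]))
        contig = assemble_target(target, recruited, m=15)
        assert len(contig.sequence) == 420
        assert contig.left_ext + contig.right_ext == 270

    def test_no_recruited_reads_returns_none(self):
        target = TargetRecord("t", TARGET51)
        assert assemble_target(target, [], m=15) is None

    def test_target_fidelity(self):
        ref = simulate_reference(SimulationConfig(seed=3, reference_length=400))
        target = TargetRecord("t", ref[100:200])
        recruited, _ = recruit(tile_reads(ref, 36), build_index([target]))
        contig = assemble_target(target, recruited)
        s, e = contig.target_span
        assert contig.sequence[s:e] == target.sequence

    def test_read_order_permutation_invariance(self):
        ref = simulate_reference(SimulationConfig(seed=4, reference_length=400))
        target = TargetRecord("t", ref[150:250])
        reads = tile_reads(ref, 40)
        rng = np.random.default_rng(0)
        fwd, _ = recruit(reads, build_index([target]))
        shuffled = list(reads)
        rng.shuffle(shuffled)
        rev, _ = recruit(shuffled, build_index([target]))
        c1 = assemble_target(target, fwd)
        c2 = assemble_target(target, rev)
        assert c1.sequence == c2.sequence
        assert (c1.left_ext, c1.right_ext) == (c2.left_ext, c2.right_ext)

    def test_strand_symmetry(self):
        """Assembling the reverse-complement target mirrors the contig."""
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, reference_length=300, read_length=36,
                                   depth=25.0, error_rate=0.0)
            ref = simulate_reference(cfg)
            reads = simulate_reads(ref, cfg)
            fwd_t = TargetRecord("f", ref[110:190])
            rev_t = TargetRecord("r", revcomp(ref[110:190]))
            fwd_rec, _ = recruit(reads, build_index([fwd_t]))
            rev_rec, _ = recruit(reads, build_index([rev_t]))
            fwd_c = assemble_target(fwd_t, fwd_rec)
            rev_c = assemble_target(rev_t, rev_rec)
            if fwd_c is None:
                assert rev_c is None
                continue
            assert rev_c.sequence == revcomp(fwd_c.sequence)
            assert (rev_c.left_ext, rev_c.right_ext) == (fwd_c.right_ext, fwd_c.left_ext)

    def test_mismatch_spike_never_alters_in_target_consensus(self):
        """Reads with one in-target mismatch are excluded entirely."""
        ref = simulate_reference(SimulationConfig(seed=6, reference_length=300))
        target = TargetRecord("t", ref[100:200])
        reads = tile_reads(ref, 36)
        baseline = assemble_target(target, recruit(reads, build_index([target]))[0])
        spiked = list(reads)
        for i in range(110, 140):  # reads overlapping the target with 1 mismatch
            frag = ref[i : i + 36]
            pos = 18
            bad = frag[:pos] + ("A" if frag[pos] != "A" else "C") + frag[pos + 1 :]
            spiked.append(ReadRecord(f"bad{i}", bad, "spike"))
        contig = assemble_target(target, recruit(spiked, build_index([target]))[0])
        s, e = contig.target_span
        bs, be = baseline.target_span
        assert contig.sequence[s:e] == baseline.sequence[bs:be] == target.sequence
        assert contig.depth[s:e] == baseline.depth[bs:be]

    def test_report_trim_drops_low_depth_target_ends(self):
        """With c=2, in-target positions covered by a single read are trimmed."""
        target = TargetRecord("t", TARGET51)
        reads = [ReadRecord(f"r{i}", TARGET51[10:46], "mem") for i in range(2)]
        reads.append(ReadRecord("lone", TARGET51[0:20], "mem"))
        recruited, _ = recruit(reads, build_index([target]))
        contig = assemble_target(target, recruited, c=2)
        assert contig.axis_start == 10
        assert contig.sequence == TARGET51[10:46]
        assert contig.left_ext == 0 and contig.right_ext == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_extension_bound_property(self, seed):
        """left/right extension never exceeds max read length − m."""
        cfg = SimulationConfig(seed=seed, reference_length=250, read_length=36,
                               depth=20.0, error_rate=0.02)
        ref = simulate_reference(cfg)
        reads = simulate_reads(ref, cfg)
        target = TargetRecord("t", ref[90:170])
        recruited, _ = recruit(reads, build_index([target]))
        m = 15
        contig = assemble_target(target, recruited, m=m)
        if contig is not None:
            bound = max(len(r.read.sequence) for r in recruited) - m
            assert contig.left_ext <= bound
            assert contig.right_ext <= bound
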