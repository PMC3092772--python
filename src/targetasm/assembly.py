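"""Stringent localized assembly anchored to a target sequence.

Each target defines a coordinate axis: position 0 is the target's first base,
positions < 0 are left flank, positions >= L right flank. Recruited reads are
placed on this axis by their matching word, oriented onto the plus strand, and
accepted only if they (a) overlap the target by at least ``m`` bases and
(b) agree with the target at EVERY in-target position they cover — the
perfect-agreement rule that makes a successful assembly itself the evidence
that the interrogated variant is present in the read set.

Per-position base tallies over target and flanks (the coverage table) drive
the consensus. Inside the target the consensus is the target verbatim; outside
it the consensus grows outward one position at a time under a majority rule:
a flank position is appended iff its depth is at least ``o`` (default 2) and
the most represented base accounts for at least a fraction ``r`` (default 0.7)
of that depth. The first failing position terminates that direction
permanently, so extension is single-pass and bounded by read_length − m per
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import revcomp
from .recruitment import RecruitedRead
from .sequence_io import TargetRecord

_RATIO_EPS = 1e-9


@dataclass(frozen=True)
class PlacedRead:
    """A read fixed on the target axis, oriented onto the plus strand."""

    read_id: str
    source_file: str
    strand: str  # '+' or '-'
    start: int  # 0-based on the target axis; may be negative (left flank)
    oriented_sequence: str

    @property
    def end(self) -> int:
        """Exclusive end coordinate on the target axis."""
        return self.start + len(self.oriented_sequence)


class CoverageTable:
    """Per-position {A,C,G,T} tallies over the target axis (flanks included).

    N bases never enter the tallies (they still occupy the read's span for
    spanning-read bookkeeping elsewhere), so depth at a position is the sum
    of its four base counts.
    """

    def __init__(self) -> None:
        self._counts: dict[int, dict[str, int]] = {}

    def add_read(self, placed: PlacedRead) -> None:
        for j, base in enumerate(placed.oriented_sequence):
            if base == "N":
                continue
            pos = placed.start + j
            bucket = self._counts.setdefault(pos, {})
            bucket[base] = bucket.get(base, 0) + 1

    def counts(self, pos: int) -> dict[str, int]:
        return self._counts.get(pos, {})

    def depth(self, pos: int) -> int:
        return sum(self._counts.get(pos, {}).values())

    def positions(self) -> list[int]:
        return sorted(self._counts)

    def __len__(self) -> int:
        return len(self._counts)


@dataclass
class Contig:
    """Final consensus for one target: target slice plus bidirectional flanks."""

    contig_id: str
    target: TargetRecord
    sequence: str
    axis_start: int  # target-axis coordinate of contig position 0
    left_ext: int  # flank bases reported left of the target region
    right_ext: int  # flank bases reported right of the target region
    depth: list[int] = field(default_factory=list)
    base_counts: list[dict[str, int]] = field(default_factory=list)
    reads: list[PlacedRead] = field(default_factory=list)

    @property
    def target_span(self) -> tuple[int, int]:
        """0-based half-open bounds of the reported target region on the contig."""
        return self.left_ext, len(self.sequence) - self.right_ext


def place_read(
    rr: RecruitedRead, target: TargetRecord, m: int = 15, k: int = 15
) -> PlacedRead | None:
    """Place one recruited read on a target's axis, or reject it.

    A '+' word hit at offset ``i`` anchors the read's prefix at ``i``; a '-'
    hit reverse-complements the read so its LAST k bases sit at [i, i+k),
    giving start ``i + k − read_length``. A candidate is accepted iff its
    in-target overlap is >= m and every overlapping in-target base matches the
    target exactly. Among accepted candidates the largest in-target overlap
    wins, ties broken by smallest start. Returns None if no candidate is
    accepted (a normal outcome, not an error).
    """
    seq = rr.read.sequence
    length = len(seq)
    tseq = target.sequence
    L = len(tseq)
    best: tuple[int, int, PlacedRead] | None = None  # (-overlap, start, placed)
    rc_cache: str | None = None
    seen: set[tuple[str, int]] = set()
    for hit in rr.candidate_hits:
        if hit.target_id != target.target_id:
            continue
        if hit.strand == "+":
            start = hit.offset
            oriented = seq
        else:
            if rc_cache is None:
                rc_cache = revcomp(seq)
            oriented = rc_cache
            start = hit.offset + k - length
        if (hit.strand, start) in seen:
            continue
        seen.add((hit.strand, start))
        lo = max(start, 0)
        hi = min(start + length, L)
        overlap = hi - lo
        if overlap < m:
            continue
        if oriented[lo - start : hi - start] != tseq[lo:hi]:
            continue
        key = (-overlap, start)
        if best is None or key < (best[0], best[1]):
            best = (
                -overlap,
                start,
                PlacedRead(rr.read.read_id, rr.read.source_file, hit.strand, start, oriented),
            )
    return best[2] if best else None


def build_coverage(placed: list[PlacedRead]) -> CoverageTable:
    """Tally every oriented base of every placed read at its axis position."""
    cov = CoverageTable()
    for pr in placed:
        cov.add_read(pr)
    return cov


def _call_flank_base(counts: dict[str, int], o: int, r: float) -> str | None:
    """Majority-rule call at one flank position; None terminates extension.

    Accept iff depth >= o and count(top)/depth >= r. When several bases tie
    for top (only satisfiable for r <= 0.5 at depth >= 2) the alphabetically
    first tying base is chosen.
    """
    depth = sum(counts.values())
    if depth < o:
        return None
    top = max(counts.values())
    if top + _RATIO_EPS < r * depth:
        return None
    return next(b for b in "ACGT" if counts.get(b, 0) == top)


def extend_consensus(
    cov: CoverageTable, target: TargetRecord, o: int = 2, r: float = 0.7
) -> Contig:
    """Derive the consensus: target verbatim inside, majority-rule flanks outside.

    Walks left from position −1 and right from position L, appending a flank
    base only while depth >= o and the top base's fraction of depth is >= r;
    the first failing position stops that direction permanently.
    """
    L = target.length
    left: list[str] = []
    pos = -1
    while True:
        base = _call_flank_base(cov.counts(pos), o, r)
        if base is None:
            break
        left.append(base)
        pos -= 1
    right: list[str] = []
    pos = L
    while True:
        base = _call_flank_base(cov.counts(pos), o, r)
        if base is None:
            break
        right.append(base)
        pos += 1
    left.reverse()
    sequence = "".join(left) + target.sequence + "".join(right)
    axis_start = -len(left)
    depth = [cov.depth(axis_start + i) for i in range(len(sequence))]
    counts = [dict(cov.counts(axis_start + i)) for i in range(len(sequence))]
    return Contig(
        contig_id=f"{target.target_id}.contig",
        target=target,
        sequence=sequence,
        axis_start=axis_start,
        left_ext=len(left),
        right_ext=len(right),
        depth=depth,
        base_counts=counts,
    )


def _longest_run_at_least(values: list[int], threshold: int) -> tuple[int, int] | None:
    """Longest (leftmost on tie) contiguous run with values >= threshold."""
    best: tuple[int, int] | None = None
    start = None
    for i, v in enumerate(values + [threshold - 1]):
        if v >= threshold:
            if start is None:
                start = i
        elif start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best


def assemble_target(
    target: TargetRecord,
    recruited: list[RecruitedRead],
    m: int = 15,
    o: int = 2,
    r: float = 0.7,
    c: int = 1,
    k: int = 15,
) -> Contig | None:
    """Full per-target assembly: place -> tally -> consensus -> report trim.

    ``c`` is the minimum depth for an in-target position to be *reported*: the
    contig keeps the longest contiguous in-target run with depth >= c
    (leftmost on ties), and a flank is reported only when the kept run reaches
    that side of the target. Returns None when no read places.
    """
    placed = []
    for rr in recruited:
        pr = place_read(rr, target, m=m, k=k)
        if pr is not None:
            placed.append(pr)
    if not placed:
        return None
    cov = build_coverage(placed)
    contig = extend_consensus(cov, target, o=o, r=r)
    contig.reads = placed
    L = target.length
    run = _longest_run_at_least([cov.depth(p) for p in range(L)], c)
    if run is None:
        return None
    s, e = run
    if s == 0 and e == L:
        return contig
    left_ext = contig.left_ext if s == 0 else 0
    right_ext = contig.right_ext if e == L else 0
    lo = (s - left_ext) - contig.axis_start
    hi = (e + right_ext) - contig.axis_start
    contig.sequence = contig.sequence[lo:hi]
    contig.depth = contig.depth[lo:hi]
    contig.base_counts = contig.base_counts[lo:hi]
    contig.axis_start = s - left_ext
    contig.left_ext = left_ext
    contig.right_ext = right_ext
    return contig
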