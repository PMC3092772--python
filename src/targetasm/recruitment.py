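"""Single-pass read recruitment.

The read stream is traversed exactly once. A read is retained if and only if
its first k bases exactly match some indexed target word; the match is
anchored to the read's literal prefix (not any internal k-mer), which is what
bounds flank extension at read_length − m per side downstream. Opposite-strand
reads are captured through the index's minus-strand words, so the read itself
is never reverse-complemented here.

Exact duplicate reads are all retained and all counted: depth is a count of
reads, not of distinct sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .sequence_io import ReadRecord
from .target_index import WordHit, WordIndex


@dataclass
class RecruitedRead:
    """A retained read together with every candidate word hit it matched."""

    read: ReadRecord
    candidate_hits: list[WordHit]

    def hits_on(self, target_id: str) -> list[WordHit]:
        return [h for h in self.candidate_hits if h.target_id == target_id]


@dataclass
class RecruitmentStats:
    reads_seen: int = 0
    reads_retained: int = 0
    per_target: dict[str, int] = field(default_factory=dict)


def recruit(
    read_stream: Iterable[ReadRecord], index: WordIndex
) -> tuple[list[RecruitedRead], RecruitmentStats]:
    """Retain every read whose first k bases match an indexed word.

    Reads shorter than k, or with an N among their first k bases, are never
    retained (N is never indexed). Stats report reads seen, reads retained,
    and per-target candidate counts (a read counts once per target it hits).
    """
    k = index.k
    table = index.table
    retained: list[RecruitedRead] = []
    stats = RecruitmentStats()
    for read in read_stream:
        stats.reads_seen += 1
        if len(read.sequence) < k:
            continue
        hits = table.get(read.sequence[:k])
        if not hits:
            continue
        retained.append(RecruitedRead(read, list(hits)))
        stats.reads_retained += 1
        for target_id in {h.target_id for h in hits}:
            stats.per_target[target_id] = stats.per_target.get(target_id, 0) + 1
    return retained, stats


def write_recruited_fasta(recruited: list[RecruitedRead], path: str) -> None:
    """Optional debugging sidecar: retained reads as FASTA."""
    with open(path, "w") as fh:
        for rr in recruited:
            fh.write(f">{rr.read.read_id}\n{rr.read.sequence}\n")
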