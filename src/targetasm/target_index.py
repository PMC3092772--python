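"""Word index over target sequences.

Every k-length word (default k=15) of each target's plus and minus strand is
stored in a hash table mapping word -> list of (target, strand, offset) hits.
The index is the recruitment key space: a read joins the assembly only if its
first k bases match one of these words exactly. k=15 trades speed against
specificity; 4^15 ≈ 10^9 keys make spurious prefix matches rare, while
low-complexity targets still draw in extra reads.

Offsets are always expressed on the target's plus strand: a minus-strand hit
at offset ``i`` stores the reverse complement of ``target[i:i+k]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .dna import revcomp
from .sequence_io import TargetRecord

LOW_SPECIFICITY_K = 11


@dataclass(frozen=True)
class WordHit:
    """Origin of one indexed word: target, strand, plus-strand start offset."""

    target_id: str
    strand: str  # '+' or '-'
    offset: int  # 0-based start of the word on the target plus strand


@dataclass
class WordIndex:
    """Hash table from k-length DNA word to all its (target, strand, offset) hits."""

    k: int = 15
    table: dict[str, list[WordHit]] = field(default_factory=dict)

    def lookup(self, word: str) -> list[WordHit]:
        if len(word) != self.k:
            raise ValueError(f"query length {len(word)} != word size k={self.k}")
        return self.table.get(word, [])

    def __len__(self) -> int:
        return len(self.table)


def extract_words(target: TargetRecord, k: int = 15) -> list[tuple[str, WordHit]]:
    """All 2·(L−k+1) words of a target: plus strand and minus strand.

    The plus-strand entry at offset ``i`` is ``target[i:i+k]``; the
    minus-strand entry at the same offset is its reverse complement. Every
    occurrence is returned, including duplicate words from internal repeats.
    """
    seq = target.sequence
    entries: list[tuple[str, WordHit]] = []
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        entries.append((word, WordHit(target.target_id, "+", i)))
        entries.append((revcomp(word), WordHit(target.target_id, "-", i)))
    return entries


def build_index(targets: list[TargetRecord], k: int = 15) -> WordIndex:
    """Build the word index over a list of targets.

    A word shared by several targets (or several offsets of one target) maps
    to every hit; disambiguation happens at placement time. Word sizes below
    11 emit a low-specificity warning.
    """
    if k < LOW_SPECIFICITY_K:
        warnings.warn(
            f"word size k={k} is low-specificity and may recruit many unrelated reads",
            stacklevel=2,
        )
    index = WordIndex(k=k)
    for target in targets:
        for word, hit in extract_words(target, k):
            index.table.setdefault(word, []).append(hit)
    return index


def lookup(index: WordIndex, word: str) -> list[WordHit]:
    """Exact-match lookup; words containing N never match."""
    return index.lookup(word)
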