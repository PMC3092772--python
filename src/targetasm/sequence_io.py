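"""On-disk formats: read streams, target FASTA, and the four assembly output files.

Reads arrive as FASTA or FASTQ (optionally gzip-compressed) listed in a
file-of-filenames, one path per line. Targets are a multi-FASTA. Assembled
contigs are written as a FASTA plus three tab-separated text files (read
positions, per-base coverage, and a modified pileup).

Quality strings are parsed but discarded: the assembler never uses them.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dna import is_acgt, sanitize_read
from .errors import InputError, TargetValidationError

logger = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, uppercased {A,C,G,T,N} sequence, source file."""

    read_id: str
    sequence: str
    source_file: str


@dataclass(frozen=True)
class TargetRecord:
    """One user-supplied target sequence (pure ACGT, length >= word size).

    ``meta`` carries optional design metadata (e.g. a junction offset for
    breakpoint targets, or the focal allele of an SNV target).
    """

    target_id: str
    sequence: str
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _validate_target(target_id: str, seq: str, k: int) -> str:
    seq = seq.upper()
    if len(seq) < k:
        raise TargetValidationError(
            f"target {target_id!r} shorter than word size: length {len(seq)} < k={k}"
        )
    if not is_acgt(seq):
        raise TargetValidationError(
            f"target {target_id!r} contains characters outside A/C/G/T"
        )
    return seq


def load_targets(path: str | os.PathLike, k: int = 15) -> list[TargetRecord]:
    """Load target sequences from a multi-FASTA file.

    Order is preserved. Duplicate IDs are disambiguated by appending an
    ordinal suffix (``id.2``, ``id.3``, ...) with a logged warning. Targets
    shorter than ``k`` or containing non-ACGT characters are rejected.
    """
    if not os.path.exists(path):
        raise InputError(f"targets file not found: {path}")
    targets: list[TargetRecord] = []
    seen: dict[str, int] = {}
    with _open_maybe_gzip(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            tokens = title.split()
            target_id = tokens[0] if tokens else title
            # recover key=value design metadata (kind, focal, allele, junction)
            meta: dict = {}
            for token in tokens[1:]:
                if "=" in token:
                    key, _, value = token.partition("=")
                    meta[key] = int(value) if value.lstrip("-").isdigit() else value
            n = seen.get(target_id, 0) + 1
            seen[target_id] = n
            if n > 1:
                logger.warning(
                    "duplicate target id %r renamed to %r", target_id, f"{target_id}.{n}"
                )
                target_id = f"{target_id}.{n}"
            targets.append(
                TargetRecord(target_id, _validate_target(target_id, seq, k), meta)
            )
    if not targets:
        raise InputError(f"no targets found in {path}")
    return targets


def _open_maybe_gzip(path: str | os.PathLike) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path)


def _parse_read_file(path: str) -> Iterator[ReadRecord]:
    handle = _open_maybe_gzip(path)
    with handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            records: Iterable[tuple[str, str]] = SimpleFastaParser(handle)
        elif first == "@":
            records = ((t, s) for t, s, _q in FastqGeneralIterator(handle))
        elif first == "":
            return
        else:
            raise InputError(
                f"{path}: cannot detect format (first character {first!r}, "
                "expected '>' for FASTA or '@' for FASTQ)"
            )
        ordinal = 0
        try:
            for title, seq in records:
                ordinal += 1
                read_id = title.split()[0] if title.split() else f"read{ordinal}"
                if not seq:
                    raise InputError(f"{path}: empty sequence at record ~{ordinal}")
                yield ReadRecord(read_id, sanitize_read(seq), path)
        except ValueError as exc:  # malformed FASTQ record
            raise InputError(f"{path}: malformed record near ~{ordinal + 1}: {exc}") from exc


def stream_reads(fof_path: str | os.PathLike) -> Iterator[ReadRecord]:
    """Lazily yield reads from every file listed in a file-of-filenames.

    One path per line; blank lines and ``#`` comments are skipped. Each file
    is auto-detected as FASTA or FASTQ (gzip accepted). Memory use is
    independent of the total read count.
    """
    if not os.path.exists(fof_path):
        raise InputError(f"file of filenames not found: {fof_path}")
    base = os.path.dirname(os.path.abspath(fof_path))
    paths: list[str] = []
    with open(fof_path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not os.path.isabs(line):
                line = os.path.join(base, line)
            paths.append(line)
    if not paths:
        raise InputError(f"no input read files listed in {fof_path}")
    for path in paths:
        if not os.path.exists(path):
            raise InputError(f"read file listed in {fof_path} not found: {path}")
    for path in paths:
        yield from _parse_read_file(path)


# ---------------------------------------------------------------------------
# output files


def _header(handle: IO[str], columns: list[str], run_info: dict | None) -> None:
    if run_info:
        handle.write("# config: " + " ".join(f"{k}={v}" for k, v in run_info.items()) + "\n")
    handle.write("# " + "\t".join(columns) + "\n")


def contig_fasta_header(contig) -> str:
    span_start, span_end = contig.target_span
    return (
        f"{contig.contig_id} target={contig.target.target_id} "
        f"length={len(contig.sequence)} reads={len(contig.reads)} "
        f"target_span={span_start + 1}-{span_end}"
    )


def write_outputs(contigs: list, out_prefix: str, run_info: dict | None = None) -> dict[str, str]:
    """Write the four output files for a set of assembled contigs.

    ``{prefix}.contigs.fa``  – consensus sequences, headers carrying target id,
    length, contributing read count and 1-based inclusive target span.
    ``{prefix}.readpos.tsv`` – placement of every contributing read on its contig.
    ``{prefix}.coverage.tsv`` – per-position depth.
    ``{prefix}.pileup.tsv``  – per-position base tallies relative to the target
    frame (negative ``target_rel`` = left flank, >= target length = right flank).
    """
    out_dir = os.path.dirname(os.path.abspath(out_prefix))
    if not os.path.isdir(out_dir):
        raise InputError(f"output directory does not exist: {out_dir}")
    paths = {
        "contigs": f"{out_prefix}.contigs.fa",
        "readpos": f"{out_prefix}.readpos.tsv",
        "coverage": f"{out_prefix}.coverage.tsv",
        "pileup": f"{out_prefix}.pileup.tsv",
    }
    # contigs.fa stays comment-free so any strict FASTA parser can read it;
    # the run config is recorded in the three TSV headers instead
    with open(paths["contigs"], "w") as fa:
        for contig in contigs:
            fa.write(f">{contig_fasta_header(contig)}\n{contig.sequence}\n")
    with open(paths["readpos"], "w") as fh:
        _header(fh, ["read_id", "source_file", "contig_id", "start", "strand"], run_info)
        for contig in contigs:
            for placed in contig.reads:
                start_on_contig = placed.start - contig.axis_start
                fh.write(
                    f"{placed.read_id}\t{placed.source_file}\t{contig.contig_id}\t"
                    f"{start_on_contig}\t{placed.strand}\n"
                )
    with open(paths["coverage"], "w") as fh:
        _header(fh, ["contig_id", "position", "depth"], run_info)
        for contig in contigs:
            for i, depth in enumerate(contig.depth):
                fh.write(f"{contig.contig_id}\t{i + 1}\t{depth}\n")
    with open(paths["pileup"], "w") as fh:
        _header(
            fh,
            ["contig_id", "position", "target_rel", "target_base",
             "consensus_base", "depth", "counts"],
            run_info,
        )
        for contig in contigs:
            tseq = contig.target.sequence
            for i in range(len(contig.sequence)):
                axis = contig.axis_start + i
                tbase = tseq[axis] if 0 <= axis < len(tseq) else "-"
                counts = contig.base_counts[i]
                counted = ",".join(
                    f"{b}:{counts[b]}" for b in "ACGT" if counts.get(b, 0)
                ) or "."
                fh.write(
                    f"{contig.contig_id}\t{i + 1}\t{axis}\t{tbase}\t"
                    f"{contig.sequence[i]}\t{contig.depth[i]}\t{counted}\n"
                )
    return paths


def write_fasta(records: Iterable[tuple[str, str]], path: str,
                run_info: dict | None = None) -> None:
    """Write (id_or_header, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        if run_info:
            fh.write("; config: " + " ".join(f"{k}={v}" for k, v in run_info.items()) + "\n")
        for title, seq in records:
            fh.write(f">{title}\n{seq}\n")
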