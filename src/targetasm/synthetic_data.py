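"""Synthetic references, implanted variants, and stranded read sets.

The generator emulates the statistical structure of the read sets the
assembler is built for — short (31–76 nt) unpaired reads at 5–36× depth with
independent per-base substitution errors, drawn from both strands — so every
stage of the pipeline can be exercised offline against known ground truth.
It does not model platform-specific error profiles, quality scores, indel
errors or paired-end structure.

A single integer seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dna import BASES, revcomp
from .sequence_io import ReadRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated read set.

    depth is total fold-coverage of the (first) reference allele; for an
    allele mixture, ``allele_fraction`` is the probability that a read is
    drawn from the second (alternate) allele. ``strand_balance`` is the
    probability of a plus-strand read; minus-strand reads are emitted
    reverse-complemented, as a sequencer would.
    """

    seed: int
    reference_length: int = 500
    read_length: int = 36
    depth: float = 30.0
    error_rate: float = 0.01
    allele_fraction: float = 0.5
    strand_balance: float = 0.5

    def __post_init__(self) -> None:
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.allele_fraction <= 1:
            raise ValueError("allele_fraction must be in [0, 1]")
        if not 0 <= self.strand_balance <= 1:
            raise ValueError("strand_balance must be in [0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one implanted event."""

    kind: str  # snv | deletion | fusion
    position: int  # 0-based focal position / first deleted base / junction
    ref_allele: str = ""
    alt_allele: str = ""
    deletion_length: int = 0
    junction: int | None = None


def _rng(seed: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, salt])


def simulate_reference(cfg: SimulationConfig, salt: int = 0) -> str:
    """Uniform-random ACGT string of cfg.reference_length, seed-reproducible.

    ``salt`` derives independent references (e.g. a fusion partner) from the
    same seed.
    """
    rng = _rng(cfg.seed, salt)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, cfg.reference_length)])


def implant_snv(
    reference: str, position: int, alt_base: str | None = None, seed: int = 0
) -> tuple[str, VariantTruth]:
    """Substitute one base; returns the mutant sequence and its truth record."""
    if not 0 <= position < len(reference):
        raise ValueError(f"SNV position {position} outside reference")
    ref_base = reference[position]
    if alt_base is None:
        choices = [b for b in BASES if b != ref_base]
        alt_base = choices[_rng(seed, 1).integers(0, 3)]
    if alt_base == ref_base:
        raise ValueError("alt base equals reference base")
    mutant = reference[:position] + alt_base + reference[position + 1 :]
    return mutant, VariantTruth("snv", position, ref_base, alt_base)


def implant_deletion(
    reference: str, position: int, length: int
) -> tuple[str, VariantTruth]:
    """Delete ``length`` bases starting at ``position``; junction recorded."""
    if length <= 0:
        raise ValueError("deletion length must be positive")
    if not 0 <= position <= len(reference) - length:
        raise ValueError("deletion span outside reference")
    mutant = reference[:position] + reference[position + length :]
    return mutant, VariantTruth(
        "deletion", position,
        ref_allele=reference[position : position + length],
        deletion_length=length, junction=position,
    )


def make_fusion(
    reference_a: str, reference_b: str, break_a: int, break_b: int
) -> tuple[str, VariantTruth]:
    """Chimaera = reference_a[:break_a] + reference_b[break_b:], junction at break_a."""
    if not 0 < break_a <= len(reference_a):
        raise ValueError("break_a outside reference A")
    if not 0 <= break_b < len(reference_b):
        raise ValueError("break_b outside reference B")
    fused = reference_a[:break_a] + reference_b[break_b:]
    return fused, VariantTruth("fusion", break_a, junction=break_a)


def implant_variant(reference: str, kind: str, **kwargs) -> tuple[str, VariantTruth]:
    """Dispatch on variant kind: snv / deletion / fusion."""
    if kind == "snv":
        return implant_snv(reference, **kwargs)
    if kind == "deletion":
        return implant_deletion(reference, **kwargs)
    if kind == "fusion":
        return make_fusion(reference, **kwargs)
    raise ValueError(f"unknown variant kind {kind!r}")


def simulate_reads(
    alleles: str | list[str],
    cfg: SimulationConfig,
    source_name: str = "simulated",
) -> list[ReadRecord]:
    """Draw stranded reads from one allele or a two-allele mixture.

    The read count is round(depth · len(first allele) / read_length); starts
    are uniform over valid positions of the chosen allele; each read comes
    from the plus or minus strand per ``strand_balance`` (minus reads are
    reverse-complemented before emission); substitution errors are applied
    per base at ``error_rate``.
    """
    if isinstance(alleles, str):
        alleles = [alleles]
    if not alleles:
        raise ValueError("at least one allele required")
    for allele in alleles:
        if cfg.read_length > len(allele):
            raise ValueError(
                f"read length {cfg.read_length} exceeds allele length {len(allele)}"
            )
    rng = _rng(cfg.seed, 2)
    n_reads = round(cfg.depth * len(alleles[0]) / cfg.read_length)
    base_arr = np.array(list(BASES))
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        if len(alleles) == 1:
            allele = alleles[0]
        else:
            allele = alleles[1] if rng.random() < cfg.allele_fraction else alleles[0]
        start = int(rng.integers(0, len(allele) - cfg.read_length + 1))
        seq = allele[start : start + cfg.read_length]
        if cfg.error_rate > 0:
            chars = np.array(list(seq))
            hits = np.flatnonzero(rng.random(cfg.read_length) < cfg.error_rate)
            for j in hits:
                alternatives = [b for b in BASES if b != chars[j]]
                chars[j] = alternatives[int(rng.integers(0, 3))]
            seq = "".join(chars)
        strand = "+" if rng.random() < cfg.strand_balance else "-"
        if strand == "-":
            seq = revcomp(seq)
        reads.append(ReadRecord(f"sim{i}_{start}{strand}", seq, source_name))
    return reads


def tile_reads(
    reference: str, read_length: int, copies: int = 2, source_name: str = "tiled"
) -> list[ReadRecord]:
    """Exhaustive error-free tiling: every start position, both strands.

    ``copies`` reads per (start, strand). Two copies per placement keep even
    the extreme flank positions — covered by a single distinct placement — at
    or above the default extension depth floor of 2, which is the regime the
    maximum-extension arithmetic (read_length − m per side) assumes.
    """
    reads: list[ReadRecord] = []
    for i in range(len(reference) - read_length + 1):
        frag = reference[i : i + read_length]
        for c in range(copies):
            reads.append(ReadRecord(f"tile{i}+{c}", frag, source_name))
            reads.append(ReadRecord(f"tile{i}-{c}", revcomp(frag), source_name))
    return reads


def write_fastq(reads: list[ReadRecord], path: str) -> None:
    """Write reads as 4-line FASTQ with dummy quality 'I'."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_truth(
    truths: list[VariantTruth], path: str, cfg: SimulationConfig | None = None
) -> None:
    """Write ground-truth records as TSV; the config is recorded in the header."""
    with open(path, "w") as fh:
        if cfg is not None:
            fh.write("# config: " + " ".join(f"{k}={v}" for k, v in cfg.as_dict().items()) + "\n")
        fh.write("# kind\tposition\tref_allele\talt_allele\tdeletion_length\tjunction\n")
        for t in truths:
            fh.write(
                f"{t.kind}\t{t.position}\t{t.ref_allele}\t{t.alt_allele}\t"
                f"{t.deletion_length}\t{'' if t.junction is None else t.junction}\n"
            )
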