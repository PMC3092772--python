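"""Construct target sequences for the three interrogation patterns.

* SNV ref/alt pairs: two targets identical except at their center base, so a
  successful assembly of one target is direct evidence for that allele.
* Fusion probes: four targets sharing a known prefix and differing only in an
  ambiguous final base, used to discover unknown sequence 3' of the prefix.
* Junction/breakpoint targets: two arms concatenated across an event, so any
  read spanning the recorded junction is chimaera evidence by construction.

Variants of one locus are always supplied as separate targets; which of them
assembles reveals which allele the read set supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .dna import BASES, is_acgt
from .errors import DesignError
from .sequence_io import TargetRecord

DEFAULT_SNV_TARGET_LENGTH = 51


@dataclass(frozen=True)
class VariantSpec:
    """A variant to design targets for, described by its local context.

    ``focal`` is the 0-based position of the base under scrutiny within
    ``reference_context``. ``alt`` is the alternate allele (SNV/indel), the
    deleted span length (deletion) or the fusion partner prefix (fusion).
    """

    kind: str  # snv | indel | deletion | fusion
    reference_context: str
    focal: int
    alt: str = ""


def _check_context(context: str, k: int = 15) -> str:
    context = context.upper()
    if not is_acgt(context):
        raise DesignError("context contains characters outside A/C/G/T")
    if len(context) < 2 * k + 1:
        warnings.warn(
            f"context length {len(context)} < 2k+1={2 * k + 1}: fewer than k words "
            "overlap the focal base, reducing recruitment",
            stacklevel=3,
        )
    return context


def snv_target_pair(
    context: str,
    ref_base: str,
    alt_base: str,
    target_id: str = "snv",
    k: int = 15,
) -> tuple[TargetRecord, TargetRecord]:
    """Build a (ref, alt) target pair from an odd-length context.

    The base under scrutiny sits at the center of the context — centering
    maximizes the number of recruiting words that overlap it. The two targets
    differ only at that position.
    """
    if len(context) % 2 == 0:
        raise DesignError(f"context length must be odd, got {len(context)}")
    context = _check_context(context, k)
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    center = len(context) // 2
    if context[center] != ref_base:
        raise DesignError(
            f"context center base {context[center]!r} != ref_base {ref_base!r}"
        )
    if alt_base == ref_base:
        raise DesignError("alt_base equals ref_base")
    if alt_base not in BASES:
        raise DesignError(f"invalid alt_base {alt_base!r}")
    alt_context = context[:center] + alt_base + context[center + 1 :]
    meta = {"kind": "snv", "focal": center}
    ref = TargetRecord(f"{target_id}.ref", context, {**meta, "allele": ref_base})
    alt = TargetRecord(f"{target_id}.alt", alt_context, {**meta, "allele": alt_base})
    return ref, alt


def fusion_probe_set(
    known_prefix: str, target_id: str = "probe", k: int = 15
) -> list[TargetRecord]:
    """Four targets = known prefix + one of {A,C,G,T} as the ambiguous last base.

    Exactly the probe whose final base matches the unknown molecule should
    recruit junction reads and extend past its end into the unknown sequence.
    """
    known_prefix = known_prefix.upper()
    if not is_acgt(known_prefix):
        raise DesignError("fusion prefix contains characters outside A/C/G/T")
    if len(known_prefix) < k:
        raise DesignError(f"fusion prefix length {len(known_prefix)} < k={k}")
    return [
        TargetRecord(
            f"{target_id}.{b}",
            known_prefix + b,
            {"kind": "fusion_probe", "focal": len(known_prefix), "allele": b},
        )
        for b in BASES
    ]


def junction_target(
    left_arm: str, right_arm: str, target_id: str = "junction", k: int = 15
) -> TargetRecord:
    """Concatenate two arms across a breakpoint; the junction offset is recorded.

    Used for fusion transcripts and deletion breakpoints: the target equals
    neither source molecule beyond the junction, so reads spanning the
    recorded offset carry bases from both sides of the event.
    """
    left_arm, right_arm = left_arm.upper(), right_arm.upper()
    if not left_arm or not right_arm:
        raise DesignError("both junction arms must be non-empty")
    seq = left_arm + right_arm
    if not is_acgt(seq):
        raise DesignError("junction arms contain characters outside A/C/G/T")
    if len(seq) < k:
        raise DesignError(f"combined arm length {len(seq)} < k={k}")
    return TargetRecord(
        target_id, seq, {"kind": "junction", "junction": len(left_arm)}
    )


def targets_from_vcf(
    reference_path: str,
    vcf_path: str,
    length: int = DEFAULT_SNV_TARGET_LENGTH,
    k: int = 15,
) -> list[TargetRecord]:
    """Batch-generate ref/alt target pairs from a reference FASTA and a VCF.

    Only CHROM, POS, REF and ALT are used (first ALT allele). SNVs yield a
    centered ref/alt pair; indels place the first altered base at the center
    and splice the ALT allele into the reference context.
    """
    from cyvcf2 import VCF
    from pyfaidx import Fasta

    if length % 2 == 0:
        raise DesignError(f"target length must be odd, got {length}")
    half = length // 2
    fasta = Fasta(reference_path)
    targets: list[TargetRecord] = []
    for rec in VCF(vcf_path):
        pos0 = rec.POS - 1  # VCF POS is 1-based
        ref_allele = rec.REF.upper()
        alt_allele = rec.ALT[0].upper()
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}"
        chrom = str(fasta[rec.CHROM])
        if len(ref_allele) == 1 and len(alt_allele) == 1:
            context = chrom[pos0 - half : pos0 + half + 1].upper()
            if len(context) != length:
                raise DesignError(f"{vid}: context extends past the reference edge")
            targets.extend(snv_target_pair(context, ref_allele, alt_allele, vid, k))
        else:
            ref_ctx = chrom[pos0 - half : pos0 + half + 1].upper()
            alt_seq = (
                chrom[pos0 - half : pos0].upper()
                + alt_allele
                + chrom[pos0 + len(ref_allele) :].upper()
            )[:length]
            if len(ref_ctx) != length or len(alt_seq) != length:
                raise DesignError(f"{vid}: context extends past the reference edge")
            meta = {"kind": "indel", "focal": half}
            targets.append(TargetRecord(f"{vid}.ref", ref_ctx, {**meta, "allele": ref_allele}))
            targets.append(TargetRecord(f"{vid}.alt", alt_seq, {**meta, "allele": alt_allele}))
    return targets
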