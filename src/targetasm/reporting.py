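"""Variant-level evidence from assembled contigs.

A variant is supported by the reads that span its focal position. Reads whose
focal base sits close to a read end are unreliable, so "interior" spanning
additionally requires the focal base to lie at least ``margin`` (default 5)
bases from both read ends; presence/absence calls count interior spanning
reads only. Deletion breakpoints are summarized Table-style as A/B counts:
A = reads over the non-deleted allele target, B = reads over the breakpoint
target.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .assembly import Contig

DEFAULT_EDGE_MARGIN = 5
DEFAULT_DETECTION_THRESHOLD = 1

REPORT_COLUMNS = [
    "variant_id", "target_id", "allele",
    "n_spanning", "n_interior", "detected", "call",
]


@dataclass
class VariantSupportReport:
    """Spanning-read evidence for one target's focal position."""

    target_id: str
    focal: int
    n_spanning: int
    n_interior: int
    detected: bool
    count_A: int | None = None  # deletion: reads over the non-deleted allele
    count_B: int | None = None  # deletion: reads over the breakpoint


@dataclass
class ChimaeraReport:
    """Junction-spanning evidence: chimaeric read count and novel flank lengths."""

    n_chimaeric: int
    novel_left: int  # consensus bases reported left of the target region
    novel_right: int  # consensus bases reported right of the target region


def count_spanning(
    contig: Contig, focal: int, margin: int = DEFAULT_EDGE_MARGIN
) -> tuple[int, int]:
    """Count reads spanning the focal target position; interior = margin-safe.

    ``focal`` is a 0-based offset on the target axis. A read spans if it
    covers the position at all; it spans interiorly if the position lies at
    least ``margin`` bases from each of its ends.
    """
    if not 0 <= focal < contig.target.length:
        raise ValueError(
            f"focal position {focal} outside target [0, {contig.target.length})"
        )
    n_spanning = 0
    n_interior = 0
    for pr in contig.reads:
        if not pr.start <= focal < pr.end:
            continue
        n_spanning += 1
        if focal - pr.start >= margin and (pr.end - 1) - focal >= margin:
            n_interior += 1
    return n_spanning, n_interior


def support_report(
    contig: Contig | None,
    focal: int,
    target_id: str = "",
    margin: int = DEFAULT_EDGE_MARGIN,
    threshold: int = DEFAULT_DETECTION_THRESHOLD,
) -> VariantSupportReport:
    """Evidence report for one target; an unassembled target has zero support."""
    if contig is None:
        return VariantSupportReport(target_id, focal, 0, 0, False)
    n_spanning, n_interior = count_spanning(contig, focal, margin)
    return VariantSupportReport(
        contig.target.target_id, focal, n_spanning, n_interior, n_interior >= threshold
    )


def allele_report(
    ref_contig: Contig | None,
    alt_contig: Contig | None,
    focal: int,
    margin: int = DEFAULT_EDGE_MARGIN,
    threshold: int = DEFAULT_DETECTION_THRESHOLD,
) -> tuple[VariantSupportReport, VariantSupportReport, str]:
    """Per-allele support and a genotype-style call: both / ref-only / alt-only / no-call."""
    ref = support_report(ref_contig, focal, "ref", margin, threshold)
    alt = support_report(alt_contig, focal, "alt", margin, threshold)
    if ref.detected and alt.detected:
        call = "both"
    elif ref.detected:
        call = "ref-only"
    elif alt.detected:
        call = "alt-only"
    else:
        call = "no-call"
    return ref, alt, call


def deletion_report(
    non_deleted_contig: Contig | None,
    breakpoint_contig: Contig | None,
    focal_non_deleted: int,
    junction: int,
    margin: int = DEFAULT_EDGE_MARGIN,
    threshold: int = DEFAULT_DETECTION_THRESHOLD,
) -> VariantSupportReport:
    """A/B-style deletion summary: A over the allele target, B over the breakpoint."""
    a = support_report(non_deleted_contig, focal_non_deleted, "A", margin, threshold)
    b = support_report(breakpoint_contig, junction, "B", margin, threshold)
    return VariantSupportReport(
        target_id=b.target_id or a.target_id,
        focal=junction,
        n_spanning=b.n_spanning,
        n_interior=b.n_interior,
        detected=b.detected,
        count_A=a.n_interior,
        count_B=b.n_interior,
    )


def chimaera_report(contig: Contig, junction: int) -> ChimaeraReport:
    """Count reads with at least one base strictly on each side of a junction.

    ``junction`` is a target-axis coordinate (the first base right of the
    breakpoint). Novel flank lengths are the consensus bases reported beyond
    the target on each side — sequence not specified by the user's target.
    """
    axis_end = contig.axis_start + len(contig.sequence)
    if not contig.axis_start <= junction <= axis_end:
        raise ValueError(
            f"junction {junction} outside contig axis [{contig.axis_start}, {axis_end}]"
        )
    n = sum(1 for pr in contig.reads if pr.start < junction < pr.end)
    return ChimaeraReport(n, contig.left_ext, contig.right_ext)


def write_variant_report(rows: list[dict], path: str, run_info: dict | None = None) -> None:
    """Write the per-(variant, allele) TSV report."""
    with open(path, "w", newline="") as fh:
        if run_info:
            fh.write("# config: " + " ".join(f"{k}={v}" for k, v in run_info.items()) + "\n")
        fh.write("# " + "\t".join(REPORT_COLUMNS) + "\n")
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, delimiter="\t")
        for row in rows:
            writer.writerow(row)
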