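"""Centromere repositioning classification via gene-anchor synteny.

Homologous-gene anchor pairs project a centromere interval from one genome
onto its homologous chromosome in the other: the nearest anchors upstream
and downstream of the centromere delimit the projected span between their
partners' inner coordinates (orientation-aware, so inverted blocks project
correctly). A centromere pair is conserved when either reciprocal projection
overlaps the partner centromere, repositioned when both reciprocal
projections are disjoint from it, and unresolved when anchors are too sparse
to project.
"""

from __future__ import annotations

from dataclasses import dataclass

from .centromere_caller import arm_ratio
from .core_io import GenomicInterval


@dataclass
class AnchorPair:
    pair_id: str
    gene_a: GenomicInterval
    gene_b: GenomicInterval


@dataclass
class RepositionCall:
    chrom_pair: tuple[str, str]
    cen_a: GenomicInterval
    cen_b: GenomicInterval
    status: str  # conserved | repositioned | unresolved
    projected_a_in_b: GenomicInterval | None = None
    projected_b_in_a: GenomicInterval | None = None
    arm_ratio_a: float = float("nan")
    arm_ratio_b: float = float("nan")


def project_interval(
    interval: GenomicInterval, anchors: list[AnchorPair], direction: str = "a_to_b"
) -> GenomicInterval | None:
    """Project an interval across genomes using flanking anchors.

    Returns None when fewer than one anchor flanks the interval on each side
    (the caller treats this as unresolved).
    """
    if direction == "a_to_b":
        get_src, get_dst = (lambda p: p.gene_a), (lambda p: p.gene_b)
    else:
        get_src, get_dst = (lambda p: p.gene_b), (lambda p: p.gene_a)
    on_chrom = [p for p in anchors if get_src(p).chrom == interval.chrom]
    upstream = [p for p in on_chrom if get_src(p).end <= interval.start]
    downstream = [p for p in on_chrom if get_src(p).start >= interval.end]
    if not upstream or not downstream:
        return None
    up = max(upstream, key=lambda p: get_src(p).end)
    down = min(downstream, key=lambda p: get_src(p).start)
    b_up, b_down = get_dst(up), get_dst(down)
    if b_up.chrom != b_down.chrom:
        return None
    if b_up.start <= b_down.start:  # colinear: span between inner coordinates
        lo, hi = b_up.end, b_down.start
    else:  # inverted block: partners in descending order
        lo, hi = b_down.end, b_up.start
    if hi <= lo:  # partners abut or nest; fall back to their outer span
        lo = min(b_up.start, b_down.start)
        hi = max(b_up.end, b_down.end)
    return GenomicInterval(b_up.chrom, lo, hi)


def classify_reposition(
    cen_a: GenomicInterval,
    cen_b: GenomicInterval,
    anchors: list[AnchorPair],
    chrom_len_a: int | None = None,
    chrom_len_b: int | None = None,
) -> RepositionCall:
    """Conserved / repositioned / unresolved by reciprocal anchor projection."""
    proj_ab = project_interval(cen_a, anchors, "a_to_b")
    proj_ba = project_interval(cen_b, anchors, "b_to_a")
    overlap_ab = proj_ab is not None and proj_ab.overlaps(cen_b)
    overlap_ba = proj_ba is not None and proj_ba.overlaps(cen_a)
    if overlap_ab or overlap_ba:
        status = "conserved"
    elif proj_ab is not None and proj_ba is not None:
        status = "repositioned"
    else:
        status = "unresolved"
    return RepositionCall(
        chrom_pair=(cen_a.chrom, cen_b.chrom),
        cen_a=cen_a,
        cen_b=cen_b,
        status=status,
        projected_a_in_b=proj_ab,
        projected_b_in_a=proj_ba,
        arm_ratio_a=arm_ratio(cen_a, chrom_len_a) if chrom_len_a else float("nan"),
        arm_ratio_b=arm_ratio(cen_b, chrom_len_b) if chrom_len_b else float("nan"),
    )
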