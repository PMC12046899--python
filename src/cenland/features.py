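"""Telomere motif runs at chromosome ends and rDNA arrays by
reference-unit matching.

Plant telomeres are tandem runs of the 7-bp motif TTTAGGG (read CCCTAAA on
the opposite strand); a chromosome end assembled through the telomere shows
such a run within its distal window. rDNA arrays are located by exact-seed
matching of a reference unit (5S or 45S), retaining copies whose matched
fraction of the unit is at least 90%.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .core_io import GenomicInterval, PipelineConfig, SequenceRecord, revcomp


@dataclass
class TelomereHit:
    region: GenomicInterval
    end: str  # five_prime | three_prime
    copies: int
    strandedness: str  # TTTAGGG-run | CCCTAAA-run


@dataclass
class RdnaArray:
    region: GenomicInterval
    unit: str  # 5S | 45S
    n_units: int
    mean_coverage: float


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_run(seq: str, motif: str, exact_only: bool) -> tuple[int, int, int] | None:
    """Longest tandem run of ``motif`` in ``seq`` allowing <= 1 mismatch per
    unit and <= copies/10 mismatched units overall. Returns (start, end, copies)."""
    k = len(motif)
    best = None
    i = 0
    n = len(seq)
    while i + k <= n:
        if _hamming(seq[i : i + k], motif) > (0 if exact_only else 1):
            i += 1
            continue
        # extend unit by unit, tracking cumulative per-unit mismatches
        mismatches = []
        j = i
        while j + k <= n:
            d = _hamming(seq[j : j + k], motif)
            if d > (0 if exact_only else 1):
                break
            mismatches.append(d)
            j += k
        # longest prefix satisfying the <=1 mismatch per 10 copies budget
        total, copies = 0, 0
        for u, d in enumerate(mismatches, start=1):
            total += d
            if total <= u / 10:
                copies = u
        if copies and (best is None or copies > best[2]):
            best = (i, i + copies * k, copies)
        i = j if j > i else i + 1
    return best


def find_telomeres(
    chrom: SequenceRecord, config: PipelineConfig | None = None, exact_only: bool = False
) -> list[TelomereHit]:
    """Scan the distal windows of a chromosome for telomere motif runs.

    Both the forward motif (TTTAGGG) and its reverse complement (CCCTAAA) are
    searched; at most one hit (the longest run) is reported per end.
    """
    config = config or PipelineConfig()
    w = min(config.telomere_distal_window, chrom.length)
    motifs = {
        f"{config.telomere_motif}-run": config.telomere_motif,
        f"{revcomp(config.telomere_motif)}-run": revcomp(config.telomere_motif),
    }
    hits = []
    for end, (lo, hi) in (
        ("five_prime", (0, w)),
        ("three_prime", (max(0, chrom.length - w), chrom.length)),
    ):
        window = chrom.seq[lo:hi]
        best = None
        for strandedness, motif in motifs.items():
            run = _best_run(window, motif, exact_only)
            if run and run[2] >= config.telomere_min_copies:
                if best is None or run[2] > best[1][2]:
                    best = (strandedness, run)
        if best:
            strandedness, (s, e, copies) = best
            hits.append(
                TelomereHit(
                    GenomicInterval(chrom.id, lo + s, lo + e), end, copies, strandedness
                )
            )
    # a short chromosome can yield the same run twice; keep distinct regions
    if len(hits) == 2 and hits[0].region == hits[1].region:
        hits = hits[:1]
    return hits


# ---------------------------------------------------------------------------
# rDNA


def find_rdna(
    chrom: SequenceRecord,
    unit_seq: str,
    config: PipelineConfig | None = None,
    unit_label: str = "5S",
    seed_len: int = 15,
) -> list[RdnaArray]:
    """Locate rDNA unit copies by exact seed matching and group them into arrays.

    Seed hits sharing a diagonal (genome position minus unit position) mark a
    candidate copy; a copy is retained when its seeds cover at least
    ``rdna_min_cov`` of the unit. Retained copies closer than two unit
    lengths are merged into arrays.
    """
    config = config or PipelineConfig()
    if len(unit_seq) < 100:
        raise ValueError("rDNA unit must be >= 100 bp")
    U = len(unit_seq)
    seeds: dict[str, list[int]] = defaultdict(list)
    for i in range(U - seed_len + 1):
        seeds[unit_seq[i : i + seed_len]].append(i)
    coverage: dict[int, set[int]] = defaultdict(set)  # diagonal -> covered unit pos
    seq = chrom.seq
    for g in range(len(seq) - seed_len + 1):
        kmer = seq[g : g + seed_len]
        if kmer in seeds:
            for u in seeds[kmer]:
                coverage[g - u].update(range(u, u + seed_len))
    copies = []
    for diag in sorted(coverage):
        cov = len(coverage[diag]) / U
        if cov >= config.rdna_min_cov and diag >= 0:
            copies.append((diag, diag + U, cov))
    # tandem exact copies also produce spurious cross-copy diagonals at
    # multiples of U; collapse copies overlapping a better-covered one
    copies.sort(key=lambda c: (-(c[2]), c[0]))
    kept: list[tuple[int, int, float]] = []
    for s, e, cov in copies:
        if all(e <= ks or s >= ke for ks, ke, _ in kept):
            kept.append((s, e, cov))
    kept.sort()
    arrays = []
    for s, e, cov in kept:
        if arrays and s - arrays[-1][1] < 2 * U:
            arrays[-1][1] = e
            arrays[-1][2].append(cov)
        else:
            arrays.append([s, e, [cov]])
    return [
        RdnaArray(
            GenomicInterval(chrom.id, s, e),
            unit_label,
            len(covs),
            sum(covs) / len(covs),
        )
        for s, e, covs in arrays
    ]
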