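"""Tandem repeat array (TRA) discovery, monomer decomposition and
higher-order repeat (HOR) detection.

Discovery is k-mer based: a window is repetitive when a sufficient fraction
of its positions start a k-mer that recurs within the window, and the array
period is the modal spacing between recurrences. Within a repetitive region,
occurrences of an anchor k-mer define monomer cut points (no cumulative
drift), the cut grid is phased to the precise array start found by
period-offset self-matching, and the consensus is a per-column majority vote
refined once against the cut monomers.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

from .core_io import GenomicInterval, PipelineConfig, SequenceRecord, revcomp


@dataclass
class Monomer:
    region: GenomicInterval
    seq: str
    divergence: float  # edit distance to consensus / consensus length


@dataclass
class TandemRepeatArray:
    region: GenomicInterval
    period: int
    consensus: str  # canonical orientation (lexicographically smaller)
    monomers: list[Monomer]
    strand: str
    family_label: str = ""

    @property
    def copies(self) -> int:
        return len(self.monomers)


@dataclass
class HORBlock:
    array_id: str
    copy_a: tuple[int, int]  # monomer index range, half-open
    copy_b: tuple[int, int]
    block_size: int
    divergence: float  # mean % divergence between aligned monomer pairs
    gap: int  # monomers between the two copies (negative if they overlap)


# ---------------------------------------------------------------------------
# Period detection


def detect_period(
    window: str,
    kmer_len: int = 12,
    max_period: int = 2000,
    min_period: int = 2,
    min_repeat_frac: float = 0.2,
) -> int | None:
    """Modal spacing between recurrences of repeated k-mers, or None.

    Requires that the fraction of window positions starting a repeated k-mer
    exceed ``min_repeat_frac``; periods <= ``min_period`` (homopolymers,
    dinucleotide wobble) are discarded.
    """
    n = len(window) - kmer_len + 1
    if n <= 0:
        return None
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        kmer = window[i : i + kmer_len]
        if "N" not in kmer:
            positions[kmer].append(i)
    repeated = 0
    spacing = Counter()
    for pos in positions.values():
        if len(pos) < 2:
            continue
        repeated += len(pos)
        for a, b in zip(pos, pos[1:]):
            d = b - a
            if d <= max_period:
                spacing[d] += 1
    if repeated / n <= min_repeat_frac or not spacing:
        return None
    period, _ = max(spacing.items(), key=lambda kv: (kv[1], -kv[0]))
    if period <= min_period:
        return None
    return period


# ---------------------------------------------------------------------------
# Array scanning


def _self_match(arr: np.ndarray, period: int, k: int) -> np.ndarray:
    """match[i] = 1 iff the k-mer at i equals the k-mer at i+period."""
    if len(arr) <= period + k:
        return np.zeros(0, dtype=bool)
    eq = (arr[:-period] == arr[period:]).astype(np.int32)
    win = np.convolve(eq, np.ones(k, dtype=np.int32), mode="valid")
    return win == k


def _array_edges(arr: np.ndarray, period: int, k: int, density: float = 0.3):
    """First and last self-matching positions inside a dense repetitive run."""
    match = _self_match(arr, period, k)
    if not match.any():
        return None
    w = min(2 * period, max(len(match), 1))
    dens = np.convolve(match.astype(np.int32), np.ones(w, dtype=np.int32), mode="full")[
        w - 1 :
    ] / w  # forward-looking density at each position
    good = match & (dens >= density)
    if not good.any():
        return None
    s = int(np.argmax(good))
    # backward-looking density for the right edge
    dens_b = np.convolve(match.astype(np.int32), np.ones(w, dtype=np.int32), mode="full")[
        : len(match)
    ] / w
    good_b = match & (dens_b >= density)
    l = int(len(good_b) - 1 - np.argmax(good_b[::-1]))
    return s, l + period + k  # [start, end) of the repetitive run


def _anchor_positions(region: str, k: int) -> list[int]:
    counts: Counter = Counter()
    for i in range(len(region) - k + 1):
        kmer = region[i : i + k]
        if "N" not in kmer:
            counts[kmer] += 1
    if not counts:
        return []
    anchor, _ = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    pos, start = [], 0
    while True:
        j = region.find(anchor, start)
        if j < 0:
            return pos
        pos.append(j)
        start = j + 1


def _cut_grid(anchors: list[int], period: int, start: int, end: int) -> list[int]:
    """Monomer start positions: the anchor grid shifted into phase with the
    array start, gaps filled at multiples of the period."""
    phase = (anchors[0] - start) % period
    cuts = []
    prev = None
    for q in anchors:
        c = q - phase
        if prev is None:
            # extend left to the array start
            lead = c
            while lead - period >= start - period // 2:
                lead -= period
            cuts.extend(range(lead, c, period))
            cuts.append(c)
        elif c > prev:
            nsteps = max(1, round((c - prev) / period))
            for t in range(1, nsteps + 1):
                cuts.append(prev + round(t * (c - prev) / nsteps))
        prev = cuts[-1]
    while cuts[-1] + period + period // 2 <= end:
        cuts.append(cuts[-1] + period)
    return [c for c in cuts if c >= start - period // 2]


def _anchored_consensus(arr8: np.ndarray, anchors: list[int], period: int) -> np.ndarray:
    """Majority-vote consensus over monomers cut at cleanly spaced anchors,
    phased so position 0 sits at the anchor k-mer."""
    slices = [
        arr8[q : q + period]
        for q, q_next in zip(anchors, anchors[1:])
        if q_next - q == period and q + period <= len(arr8)
    ]
    if not slices:
        slices = [arr8[q : q + period] for q in anchors if q + period <= len(arr8)]
    cols = np.stack(slices)
    cons = np.empty(period, dtype="S1")
    for j in range(period):
        vals, counts = np.unique(cols[:, j], return_counts=True)
        cons[j] = vals[np.argmax(counts)]
    return cons


def _refine_edge(
    arr8: np.ndarray, cons_q: np.ndarray, q0: int, period: int, coarse: int, side: str
) -> int:
    """Two-segment change-point split of per-base agreement with the phased
    consensus: array bases agree ~per-base-identity, background ~25%."""
    lo = max(0, coarse - 2 * period)
    hi = min(len(arr8), coarse + 2 * period)
    if hi <= lo:
        return coarse
    idx = np.arange(lo, hi)
    expected = cons_q[(idx - q0) % period]
    agree = arr8[lo:hi] == expected
    # log-likelihood ratio weights: in-array bases agree ~0.97, background
    # ~0.25, so an agreement scores ~+1.4 and a disagreement ~-3.6
    llr = np.where(agree, 1.4, -3.6)
    cum = np.concatenate([[0.0], np.cumsum(llr)])
    if side == "left":
        score = cum[-1] - cum  # suffix sum: bases from the split onward
    else:
        score = cum  # prefix sum: bases before the split
    return lo + int(np.argmax(score))


def _consensus(monomers: list[str], period: int) -> str:
    full = [m for m in monomers if len(m) == period] or monomers
    cols = np.array([np.frombuffer(m[:period].ljust(period, "N").encode(), dtype="S1") for m in full])
    cons = []
    for j in range(period):
        vals, counts = np.unique(cols[:, j], return_counts=True)
        cons.append(vals[np.argmax(counts)].decode())
    return "".join(cons)


def least_rotation(s: str) -> str:
    """Lexicographically smallest rotation (circular canonical form)."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def array_from_monomers(
    monomers: list[str],
    period: int,
    chrom: str = "array",
    start: int = 0,
    strand: str = "+",
    family_label: str = "",
) -> TandemRepeatArray:
    """Assemble a TandemRepeatArray from pre-cut monomer sequences."""
    cons = _consensus(monomers, period)
    out = []
    pos = start
    for m in monomers:
        out.append(
            Monomer(
                GenomicInterval(chrom, pos, pos + len(m), strand),
                m,
                monomer_divergence(m, cons),
            )
        )
        pos += len(m)
    return TandemRepeatArray(
        region=GenomicInterval(chrom, start, pos, strand),
        period=period,
        consensus=cons,
        monomers=out,
        strand=strand,
        family_label=family_label or f"sat{period}",
    )


def monomer_divergence(seq: str, consensus: str) -> float:
    if not consensus:
        return 1.0
    d = edlib.align(seq, consensus, task="distance")["editDistance"]
    return d / len(consensus)


def scan_arrays(
    chrom: SequenceRecord, config: PipelineConfig | None = None, genome_tag: str = "sat"
) -> list[TandemRepeatArray]:
    """Discover tandem repeat arrays on one chromosome.

    Sliding windows are scored by :func:`detect_period`; windows with
    compatible periods (within 10%) merge into candidate regions, which are
    then refined to exact boundaries and decomposed into monomers.
    """
    config = config or PipelineConfig()
    seq = chrom.seq
    win, step, k = config.scan_window, config.scan_step, config.kmer_len
    hits = []  # (window start, period)
    for ws in range(0, max(1, len(seq) - win + 1), step):
        p = detect_period(seq[ws : ws + win], kmer_len=k)
        if p is not None:
            hits.append((ws, p))
    if not hits:
        return []

    # merge adjacent windows with compatible periods into regions
    regions = []  # [start, end, periods]
    for ws, p in hits:
        if (
            regions
            and ws <= regions[-1][1]
            and abs(p - np.median(regions[-1][2])) <= 0.1 * np.median(regions[-1][2])
        ):
            regions[-1][1] = ws + win
            regions[-1][2].append(p)
        else:
            regions.append([ws, ws + win, [p]])

    arrays = []
    for a, b, periods in regions:
        a_ext = max(0, a - step)
        b_ext = min(len(seq), b + step)
        sub = seq[a_ext:b_ext]
        arr8 = np.frombuffer(sub.encode(), dtype="S1")
        period = int(np.median(periods))
        edges = _array_edges(arr8, period, k)
        if edges is None:
            continue
        s_coarse, e_coarse = edges
        anchors = [q + s_coarse for q in _anchor_positions(sub[s_coarse:e_coarse], k)]
        if not anchors:
            continue
        # refine the period from exact anchor spacings when possible
        diffs = Counter(
            b_ - a_ for a_, b_ in zip(anchors, anchors[1:]) if b_ - a_ <= 2 * period
        )
        if diffs:
            refined, _ = max(diffs.items(), key=lambda kv: (kv[1], -kv[0]))
            if abs(refined - period) <= 0.2 * period:
                period = refined
        # single-bp edge refinement against the anchored consensus
        cons_q = _anchored_consensus(arr8, anchors, period)
        s_rel = _refine_edge(arr8, cons_q, anchors[0], period, s_coarse, "left")
        e_rel = _refine_edge(arr8, cons_q, anchors[0], period, e_coarse, "right")
        if e_rel - s_rel < 2 * period:
            continue
        cuts = _cut_grid(anchors, period, s_rel, e_rel)
        if len(cuts) < 2:
            continue
        bounds = cuts + [cuts[-1] + period]
        monos = [sub[max(0, x) : y] for x, y in zip(bounds, bounds[1:])]
        monos = [m for m in monos if m]
        cons = _consensus(monos, period)
        # strand from the rotation-minimal (circular) canonical form, which is
        # stable under monomer phase; consensus reported in canonical orientation
        strand = (
            "+" if least_rotation(cons) <= least_rotation(revcomp(cons)) else "-"
        )
        canonical = cons if strand == "+" else revcomp(cons)
        start_abs = a_ext + max(0, bounds[0])
        end_abs = a_ext + bounds[-1]
        monomers = []
        off = max(0, bounds[0])
        for m in monos:
            monomers.append(
                Monomer(
                    GenomicInterval(chrom.id, a_ext + off, a_ext + off + len(m), strand),
                    m,
                    monomer_divergence(m, cons),
                )
            )
            off += len(m)
        arrays.append(
            TandemRepeatArray(
                region=GenomicInterval(chrom.id, start_abs, min(end_abs, len(seq)), strand),
                period=period,
                consensus=canonical,
                monomers=monomers,
                strand=strand,
                family_label=f"{genome_tag}{len(canonical)}",
            )
        )
    return arrays


def filter_arrays(
    arrays: list[TandemRepeatArray], config: PipelineConfig | None = None
) -> list[TandemRepeatArray]:
    """Retention rule: monomer length strictly > 50 bp AND copy number
    strictly > 50 (defaults; both bounds exclusive)."""
    config = config or PipelineConfig()
    return [
        a
        for a in arrays
        if a.period > config.min_monomer_len and a.copies > config.min_copies
    ]


# ---------------------------------------------------------------------------
# Higher-order repeats


def monomer_divergence_matrix(monomers: list[str], period: int) -> np.ndarray:
    """Pairwise % divergence (edit distance / period * 100), symmetric."""
    n = len(monomers)
    div = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(monomers[i], monomers[j], task="distance")["editDistance"]
            div[i, j] = div[j, i] = 100.0 * d / period
    return div


def hor_blocks_from_matrix(
    div: np.ndarray,
    min_block: int = 2,
    max_div: float = 5.0,
    array_id: str = "",
) -> list[HORBlock]:
    """Maximal same-diagonal runs of monomer pairs each within ``max_div``.

    A run of length L on diagonal offset d pairs monomers [i, i+L) with
    [i+d, i+d+L); runs shorter than ``min_block`` are dropped. The block's
    divergence is the mean over its aligned pairs.
    """
    n = div.shape[0]
    blocks = []
    for d in range(1, n):
        good = div[np.arange(0, n - d), np.arange(d, n)] <= max_div
        i = 0
        while i < n - d:
            if not good[i]:
                i += 1
                continue
            j = i
            while j < n - d and good[j]:
                j += 1
            L = j - i
            if L >= min_block:
                vals = div[np.arange(i, j), np.arange(i + d, j + d)]
                blocks.append(
                    HORBlock(
                        array_id=array_id,
                        copy_a=(i, j),
                        copy_b=(i + d, j + d),
                        block_size=L,
                        divergence=float(vals.mean()),
                        gap=d - L,
                    )
                )
            i = j
    blocks.sort(key=lambda b: (-b.block_size, b.divergence, b.copy_a, b.copy_b))
    return blocks


def detect_hors(
    array: TandemRepeatArray, config: PipelineConfig | None = None
) -> list[HORBlock]:
    config = config or PipelineConfig()
    if array.copies < 2 * config.hor_min_block:
        return []
    seqs = [m.seq for m in array.monomers]
    div = monomer_divergence_matrix(seqs, array.period)
    return hor_blocks_from_matrix(
        div,
        min_block=config.hor_min_block,
        max_div=config.hor_max_div,
        array_id=array.family_label or "array",
    )
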