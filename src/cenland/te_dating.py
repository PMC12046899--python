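"""LTR retrotransposon dating and centromeric TE statistics.

An intact LTR retrotransposon carries two long terminal repeats that were
identical at insertion; their divergence K dates the insertion via
T = K / (2 r), with r the neutral substitution rate per site per year
(default 2.5e-9). Divergence is computed over gap-free aligned columns under
raw (p-distance), JC69 or K80 models; K80 is the default, matching common
practice for LTR dating (ape's dist.dna default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm

from ._alignment import make_aligner
from .core_io import GenomicInterval

_ALIGNER = make_aligner()

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class LTRElement:
    element: GenomicInterval
    family: str  # CRM | ATHILA | LINE | other
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    identity: float = float("nan")  # percent
    K: float = float("nan")  # substitutions/site
    T: float = float("nan")  # years
    compartment: str = "non_centromeric"
    element_id: str = ""


# ---------------------------------------------------------------------------
# Alignment-level statistics


# Affine DP is quadratic; beyond this many cells, switch to edlib's banded
# unit-cost global alignment (identical columns for high-identity pairs such
# as the two repeats of one LTR element).
_DP_CELL_LIMIT = 1_000_000


def _global_columns(seq_a: str, seq_b: str):
    """(n_columns, list of gap-free aligned (a, b) character pairs)."""
    if len(seq_a) == len(seq_b):
        # ungapped pairing is the optimal affine-penalty alignment for
        # equal-length, high-identity pairs (e.g. the two LTRs of an element)
        mismatch = sum(a != b for a, b in zip(seq_a, seq_b))
        if mismatch <= 0.25 * len(seq_a):
            return len(seq_a), list(zip(seq_a, seq_b))
    if len(seq_a) * len(seq_b) <= _DP_CELL_LIMIT:
        aln = _ALIGNER.align(seq_a, seq_b)[0]
        pairs = []
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for t, q in zip(range(ts, te), range(qs, qe)):
                pairs.append((seq_a[t], seq_b[q]))
        return aln.length, pairs
    import edlib
    import re

    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    pairs = []
    n_cols = 0
    ia = ib = 0
    for length, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        length = int(length)
        n_cols += length
        if op in "=XM":
            pairs.extend(zip(seq_a[ia : ia + length], seq_b[ib : ib + length]))
            ia += length
            ib += length
        elif op == "I":  # insertion relative to target (consumes query=seq_a)
            ia += length
        else:  # D consumes seq_b
            ib += length
    return n_cols, pairs


def aligned_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical pairs over all alignment columns (gap columns count
    as non-identical)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n_cols, pairs = _global_columns(seq_a, seq_b)
    matches = sum(a == b for a, b in pairs)
    return 100.0 * matches / n_cols


def _aligned_columns(seq_a: str, seq_b: str):
    """Gap-free aligned column pairs from the global alignment."""
    return _global_columns(seq_a, seq_b)[1]


def divergence(seq_a: str, seq_b: str, model: str = "K80") -> float:
    """Substitutions/site between two sequences over gap-free aligned columns.

    raw: mismatch proportion p. JC69: -(3/4) ln(1 - 4p/3).
    K80: -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q), P transitions, Q transversions.
    """
    pairs = _aligned_columns(seq_a, seq_b)
    if not pairs:
        raise ValueError("no gap-free aligned columns")
    n = len(pairs)
    mismatch = sum(a != b for a, b in pairs)
    p = mismatch / n
    if model == "raw":
        return p
    if model == "JC69":
        arg = 1 - 4 * p / 3
        if arg <= 0:
            raise ValueError(f"saturated divergence (p={p:.3f}) under JC69")
        return -0.75 * math.log(arg)
    if model == "K80":
        ts = sum(
            a != b and ({a, b} <= _PURINES or {a, b} <= _PYRIMIDINES)
            for a, b in pairs
        )
        P, Q = ts / n, (mismatch - ts) / n
        a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
        if a1 <= 0 or a2 <= 0:
            raise ValueError(f"saturated divergence (P={P:.3f}, Q={Q:.3f}) under K80")
        return -0.5 * math.log(a1) - 0.25 * math.log(a2)
    raise ValueError(f"unknown model {model!r}")


def insertion_time(K: float, r: float = 2.5e-9) -> float:
    """T = K / (2 r) in years."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("mutation rate r must be > 0")
    return K / (2 * r)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(x, y, exact_max_n: int = 16) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Exact permutation enumeration when n+m <= ``exact_max_n``; otherwise a
    normal approximation with tie correction and continuity correction.
    Returns (rank-sum statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(n + m)
    sorted_vals = pooled[order]
    # midranks
    i = 0
    pos = 1
    while i < n + m:
        j = i
        while j < n + m and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (pos + pos + (j - i) - 1) / 2
        pos += j - i
        i = j
    w_obs = float(ranks[:n].sum())
    N = n + m
    mu = n * (N + 1) / 2

    if N <= exact_max_n:
        dev = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(N), n):
            total += 1
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-9:
                count += 1
        return w_obs, count / total

    _, tie_counts = np.unique(sorted_vals, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    sigma2 = n * m / 12 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return w_obs, 1.0
    dev = abs(w_obs - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(sigma2)
    return w_obs, min(1.0, 2 * float(norm.sf(z)))


# ---------------------------------------------------------------------------
# Element-level pipeline


def date_element(
    elem: LTRElement, genome: dict[str, str], model: str = "K80", r: float = 2.5e-9
) -> LTRElement:
    """Fill identity, K and T from the element's 5' and 3' repeats."""
    seq5 = genome[elem.ltr5.chrom][elem.ltr5.start : elem.ltr5.end]
    seq3 = genome[elem.ltr3.chrom][elem.ltr3.start : elem.ltr3.end]
    elem.identity = aligned_identity(seq5, seq3)
    elem.K = divergence(seq5, seq3, model=model)
    elem.T = insertion_time(elem.K, r)
    return elem


def assign_compartment(elements: list[LTRElement], centromeres) -> list[LTRElement]:
    """centromeric iff the element midpoint falls inside a centromere call."""
    cen_ivs = [getattr(c, "region", c) for c in centromeres]
    for e in elements:
        mid = e.element.midpoint
        e.compartment = (
            "centromeric"
            if any(iv.chrom == e.element.chrom and iv.contains_point(mid) for iv in cen_ivs)
            else "non_centromeric"
        )
    return elements


# ---------------------------------------------------------------------------
# Composition


def _subtract(iv: tuple[int, int], occupied: list[tuple[int, int]]):
    """Pieces of iv not covered by the (sorted, merged) occupied list."""
    pieces = [iv]
    for os, oe in occupied:
        nxt = []
        for s, e in pieces:
            if oe <= s or os >= e:
                nxt.append((s, e))
            else:
                if s < os:
                    nxt.append((s, os))
                if oe < e:
                    nxt.append((oe, e))
        pieces = nxt
    return pieces


def _merge_into(occupied: list[tuple[int, int]], pieces) -> list[tuple[int, int]]:
    merged = sorted(occupied + list(pieces))
    out = []
    for s, e in merged:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class CompositionReport:
    centromere: GenomicInterval
    total_bp: int
    family_bp: dict[str, int]
    family_percent: dict[str, float]
    repeat_percent: float


def centromere_composition(
    te_annotations: list[tuple[GenomicInterval, str]], centromeres
) -> list[CompositionReport]:
    """Per centromere, the fraction of bases covered by each TE family.

    Each base is credited to a single family: overlaps between annotations are
    resolved by longer-annotation priority before taking the per-family union.
    """
    reports = []
    for cen in centromeres:
        cen_iv = getattr(cen, "region", cen)
        fam_bp: dict[str, int] = {"CRM": 0, "ATHILA": 0, "LINE": 0, "other": 0}
        occupied: list[tuple[int, int]] = []
        annos = [
            (iv, fam)
            for iv, fam in te_annotations
            if iv.chrom == cen_iv.chrom and iv.overlaps(cen_iv)
        ]
        annos.sort(key=lambda a: (-(a[0].length), a[0].start))
        for iv, fam in annos:
            clipped = (max(iv.start, cen_iv.start), min(iv.end, cen_iv.end))
            fresh = _subtract(clipped, occupied)
            fam_bp[fam] = fam_bp.get(fam, 0) + sum(e - s for s, e in fresh)
            occupied = _merge_into(occupied, fresh)
        total = cen_iv.length
        covered = sum(e - s for s, e in occupied)
        reports.append(
            CompositionReport(
                centromere=cen_iv,
                total_bp=total,
                family_bp=fam_bp,
                family_percent={f: 100.0 * b / total for f, b in fam_bp.items()},
                repeat_percent=100.0 * covered / total,
            )
        )
    return reports
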