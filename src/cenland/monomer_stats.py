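"""Satellite monomer diversity statistics.

The central statistic is the per-position "variant distance": within a
multiple alignment of monomers, each column's element proportions (A, C, G,
T and gap all count as elements) are tabulated, a monomer's distance at a
column is 1 minus the proportion of its own element there, and the
per-monomer distances are cumulated over all columns.

The alignment is a consensus-anchored star alignment: every monomer is
globally aligned to the family consensus and the pairwise alignments are
projected onto consensus columns, with insertions relative to the consensus
appended as extra columns at their host position. This is deterministic and
adequate for column-proportion statistics; it is not a de novo MSA.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._alignment import make_aligner
from .te_dating import wilcoxon_rank_sum

GAP = "-"
_ELEMENTS = ("A", "C", "G", "T", "N", GAP)

_ALIGNER = make_aligner()


@dataclass
class MonomerAlignment:
    monomer_ids: list[str]
    rows: list[str]  # all equal length, over {A,C,G,T,N,-}

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class VariantProfile:
    position_proportions: list[dict[str, float]]
    per_monomer_distance: np.ndarray
    per_position_distance: np.ndarray  # monomers x positions


def _project(consensus: str, monomer: str):
    """Align monomer to consensus; return (per-consensus-position char,
    insertions host_position -> inserted string)."""
    aln = _ALIGNER.align(consensus, monomer)[0]
    t_blocks, q_blocks = aln.aligned
    chars = [GAP] * len(consensus)
    insertions: dict[int, str] = {}
    prev_t = prev_q = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q:  # unaligned query = insertion hosted before column ts
            insertions[ts] = insertions.get(ts, "") + monomer[prev_q:qs]
        for t, q in zip(range(ts, te), range(qs, qe)):
            chars[t] = monomer[q]
        prev_t, prev_q = te, qe
    if prev_q < len(monomer):
        insertions[len(consensus)] = insertions.get(len(consensus), "") + monomer[prev_q:]
    return chars, insertions


def align_monomers(
    monomers: list[str], consensus: str, ids: list[str] | None = None
) -> MonomerAlignment:
    """Consensus-anchored star alignment of monomers."""
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers")
    if not consensus:
        raise ValueError("consensus must be non-empty")
    for m in monomers:
        if not m:
            raise ValueError("empty monomer sequence")
    ids = ids or [f"m{i}" for i in range(len(monomers))]
    projected = [_project(consensus, m) for m in monomers]
    ins_width: dict[int, int] = defaultdict(int)
    for _, ins in projected:
        for host, s in ins.items():
            ins_width[host] = max(ins_width[host], len(s))
    rows = []
    for chars, ins in projected:
        row = []
        for c in range(len(consensus) + 1):
            if ins_width.get(c):
                s = ins.get(c, "")
                row.append(s.ljust(ins_width[c], GAP))
            if c < len(consensus):
                row.append(chars[c])
        rows.append("".join(row))
    return MonomerAlignment(ids, rows)


def variant_distance(aln: MonomerAlignment, skip_gap_positions: bool = False) -> VariantProfile:
    """Per-position variant distance 1 - (own element's column proportion),
    cumulated per monomer over all columns.

    With ``skip_gap_positions`` a monomer's gap columns contribute 0 to its
    own cumulative distance (the default counts gaps as elements everywhere).
    """
    mat = np.array([list(r) for r in aln.rows])
    n, L = mat.shape
    props: list[dict[str, float]] = []
    dist = np.zeros((n, L))
    for j in range(L):
        counts = Counter(mat[:, j])
        p = {e: counts.get(e, 0) / n for e in _ELEMENTS}
        props.append(p)
        for i in range(n):
            d = 1.0 - p[mat[i, j]]
            if skip_gap_positions and mat[i, j] == GAP:
                d = 0.0
            dist[i, j] = d
    return VariantProfile(props, dist.sum(axis=1), dist)


def pairwise_identity(monomers: list[str]) -> np.ndarray:
    """Global-alignment identity matrix: matches / alignment columns."""
    if len(monomers) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(monomers)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            aln = _ALIGNER.align(monomers[i], monomers[j])[0]
            counts = aln.counts()
            ident[i, j] = ident[j, i] = counts.identities / aln.length
    return ident


@dataclass
class GroupComparison:
    within_median: float
    between_median: float
    statistic: float
    p_value: float
    n_within: int
    n_between: int
    excluded_groups: list[str]


def group_compare(identities: np.ndarray, labels: list[str]) -> GroupComparison:
    """Within-group vs between-group identity comparison (two-sided
    Wilcoxon rank-sum). Groups with fewer than 2 members are excluded."""
    counts = Counter(labels)
    excluded = sorted(g for g, c in counts.items() if c < 2)
    if excluded:
        import warnings

        warnings.warn(f"groups excluded (<2 members): {excluded}")
    valid = {g for g, c in counts.items() if c >= 2}
    if len(valid) < 2:
        raise ValueError("need at least 2 groups with >= 2 members each")
    within, between = [], []
    n = len(labels)
    for i in range(n):
        if labels[i] not in valid:
            continue
        for j in range(i + 1, n):
            if labels[j] not in valid:
                continue
            (within if labels[i] == labels[j] else between).append(identities[i, j])
    stat, p = wilcoxon_rank_sum(within, between)
    return GroupComparison(
        float(np.median(within)),
        float(np.median(between)),
        stat,
        p,
        len(within),
        len(between),
        excluded,
    )


def representative_monomer(monomers_by_chrom: dict[str, list[str]]) -> dict[str, str]:
    """Per chromosome, the monomer sequence with the highest copy number
    (exact string equality; ties broken lexicographically)."""
    if not monomers_by_chrom:
        raise ValueError("empty input")
    out = {}
    for chrom, monos in monomers_by_chrom.items():
        counts = Counter(monos)
        out[chrom] = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return out


def proportional_sample(
    monomers_by_chrom: dict[str, list[str]], total_n: int, seed: int
) -> list[str]:
    """Sample monomers with per-chromosome quotas proportional to each
    chromosome's monomer count (largest-remainder rounding), uniformly
    without replacement."""
    chroms = sorted(monomers_by_chrom)
    counts = {c: len(monomers_by_chrom[c]) for c in chroms}
    total = sum(counts.values())
    if total_n > total:
        raise ValueError(f"total_n {total_n} exceeds population {total}")
    raw = {c: total_n * counts[c] / total for c in chroms}
    quota = {c: int(np.floor(raw[c])) for c in chroms}
    short = total_n - sum(quota.values())
    for c in sorted(chroms, key=lambda c: (-(raw[c] - quota[c]), c))[:short]:
        quota[c] += 1
    # cap at availability, redistributing any excess deterministically
    for c in chroms:
        quota[c] = min(quota[c], counts[c])
    rng = np.random.default_rng(seed)
    sample = []
    for c in chroms:
        idx = rng.choice(counts[c], size=quota[c], replace=False)
        sample.extend(monomers_by_chrom[c][i] for i in sorted(idx))
    return sample


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    denom = sum(counts.get(b, 0) for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence has no A/C/G/T bases")
    return (counts.get("G", 0) + counts.get("C", 0)) / denom
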