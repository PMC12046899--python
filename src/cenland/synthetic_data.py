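"""Synthetic genomes with planted truth.

Emulates the statistical structure the downstream analyses assume: satellite
tandem-repeat arrays (optionally with higher-order-repeat structure), dated
LTR retrotransposon insertions, LINE insertions, telomere motif runs at
chromosome ends, and Poisson CUT&Tag/Input count tracks with fold enrichment
over a planted centromere.

The mutation model is substitution-only by default so that truth coordinates
stay exact; a per-monomer indel rate can be enabled to exercise gap handling.
A single global seed expands into per-feature child streams keyed by a stable
hash of (chromosome name, feature index), so results do not depend on the
order features are simulated in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BinnedTrack, GenomicInterval, SequenceRecord, n_bins, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _feature_rng(seed: int, chrom: str, index: int) -> np.random.Generator:
    """Child RNG keyed by (global seed, chrom hash, feature index)."""
    return np.random.default_rng([seed, zlib.crc32(chrom.encode()), index])


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at ``rate`` per site, always to a different base."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Specs


@dataclass
class HORSpec:
    unit_size: int  # monomers per higher-order unit
    unit_repeats: int  # tandem copies of the unit
    variant_divergence: float = 0.05  # divergence between the unit's variant monomers

    def __post_init__(self):
        if self.unit_size < 2:
            raise ValueError("hor unit_size must be >= 2")


@dataclass
class SatelliteSpec:
    consensus: str
    copies: int = 1
    per_base_divergence: float = 0.0
    hor: HORSpec | None = None
    strand: str = "+"
    indel_rate: float = 0.0  # per-monomer probability of a 1-bp indel

    def __post_init__(self):
        if self.hor is not None:
            self.copies = self.hor.unit_size * self.hor.unit_repeats
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not (0 <= self.per_base_divergence < 0.5):
            raise ValueError("per_base_divergence must be in [0, 0.5)")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def monomer_len(self) -> int:
        return len(self.consensus)


@dataclass
class LTRInsertionSpec:
    position: int
    family: str  # CRM | ATHILA | other
    ltr_length: int
    internal_length: int
    age_years: float

    @property
    def total_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length


@dataclass
class LineInsertionSpec:
    position: int
    length: int


@dataclass
class ChromosomeSpec:
    name: str
    length: int
    gc: float = 0.34
    telomeres: str = "none"  # none | one_end | both_ends
    telomere_copies: int = 100
    telomere_motif: str = "TTTAGGG"
    satellites: list[tuple[int, SatelliteSpec]] = field(default_factory=list)
    ltr_insertions: list[LTRInsertionSpec] = field(default_factory=list)
    line_insertions: list[LineInsertionSpec] = field(default_factory=list)
    centromere: GenomicInterval | None = None
    mutation_rate_r: float = 2.5e-9  # substitutions/site/year, for LTR aging


@dataclass
class TruthTable:
    """Planted-feature coordinates matching the emitted sequence."""

    arrays: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    monomers: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    telomeres: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    tes: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    ltr_pairs: dict[str, tuple[GenomicInterval, GenomicInterval]] = field(
        default_factory=dict
    )
    ltr_ages: dict[str, float] = field(default_factory=dict)
    centromere: GenomicInterval | None = None


# ---------------------------------------------------------------------------
# Satellite arrays


def simulate_satellite_array(
    spec: SatelliteSpec, seed: int | np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate ``copies`` mutated monomers; return sequence and
    per-monomer (start, end) offsets within the array.

    With HOR structure, a block of ``unit_size`` distinct variant monomers is
    drawn once and tandemly repeated ``unit_repeats`` times before the
    independent per-copy mutation is applied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.hor is not None:
        variants = [
            mutate(spec.consensus, spec.hor.variant_divergence, rng)
            for _ in range(spec.hor.unit_size)
        ]
        templates = variants * spec.hor.unit_repeats
    else:
        templates = [spec.consensus] * spec.copies

    pieces, offsets = [], []
    pos = 0
    for tmpl in templates:
        mono = mutate(tmpl, spec.per_base_divergence, rng)
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            i = int(rng.integers(len(mono)))
            if rng.random() < 0.5 and len(mono) > 1:
                mono = mono[:i] + mono[i + 1 :]
            else:
                mono = mono[:i] + random_dna(1, rng) + mono[i:]
        pieces.append(mono)
        offsets.append((pos, pos + len(mono)))
        pos += len(mono)
    seq = "".join(pieces)
    if spec.strand == "-":
        seq = revcomp(seq)
        total = len(seq)
        offsets = [(total - e, total - s) for s, e in reversed(offsets)]
    return seq, offsets


# ---------------------------------------------------------------------------
# Chromosomes


def _ltr_element(
    spec: LTRInsertionSpec, r: float, gc: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Build 5'LTR-internal-3'LTR; the two LTRs start identical and each is
    mutated at r*age so their expected pairwise divergence is 2*r*age."""
    ancestral = random_dna(spec.ltr_length, rng, gc)
    per_copy = r * spec.age_years
    ltr5 = mutate(ancestral, per_copy, rng)
    ltr3 = mutate(ancestral, per_copy, rng)
    internal = random_dna(spec.internal_length, rng, gc)
    return ltr5 + internal + ltr3, spec.ltr_length, spec.ltr_length + spec.internal_length


def simulate_chromosome(
    spec: ChromosomeSpec, seed: int
) -> tuple[SequenceRecord, TruthTable]:
    """Background sequence at the stated GC with planted features spliced in.

    Features overwrite the background at their stated positions; overlapping
    features are an error. The truth table records every planted coordinate.
    """
    rng_bg = _feature_rng(seed, spec.name, 0)
    seq = np.frombuffer(random_dna(spec.length, rng_bg, spec.gc).encode(), dtype="S1").copy()
    truth = TruthTable(centromere=spec.centromere)
    placed: list[tuple[int, int, str]] = []

    def place(start: int, piece: str, label: str):
        end = start + len(piece)
        if start < 0 or end > spec.length:
            raise ValueError(f"{label} at [{start}, {end}) exceeds chromosome bounds")
        for s, e, other in placed:
            if start < e and s < end:
                raise ValueError(
                    f"planted features collide: {label} [{start},{end}) vs "
                    f"{other} [{s},{e})"
                )
        placed.append((start, end, label))
        seq[start:end] = np.frombuffer(piece.encode(), dtype="S1")

    fidx = 1
    # telomeres: TTTAGGG runs on the forward strand read 3'->: by convention the
    # 5' end carries the reverse-complement (CCCTAAA) run and the 3' end the
    # forward run, as on real plant chromosome ends.
    telo_len = spec.telomere_copies * len(spec.telomere_motif)
    if spec.telomeres in ("one_end", "both_ends"):
        piece = revcomp(spec.telomere_motif) * spec.telomere_copies
        place(0, piece, "telomere_5p")
        truth.telomeres.append(
            (GenomicInterval(spec.name, 0, telo_len), "five_prime")
        )
    if spec.telomeres == "both_ends":
        piece = spec.telomere_motif * spec.telomere_copies
        place(spec.length - telo_len, piece, "telomere_3p")
        truth.telomeres.append(
            (GenomicInterval(spec.name, spec.length - telo_len, spec.length), "three_prime")
        )

    for pos, sat in spec.satellites:
        arr_seq, offsets = simulate_satellite_array(sat, _feature_rng(seed, spec.name, fidx))
        fidx += 1
        label = f"sat{sat.monomer_len}"
        place(pos, arr_seq, label)
        truth.arrays.append(
            (GenomicInterval(spec.name, pos, pos + len(arr_seq), sat.strand), label)
        )
        for s, e in offsets:
            truth.monomers.append(
                (GenomicInterval(spec.name, pos + s, pos + e, sat.strand), label)
            )

    for k, ltr in enumerate(spec.ltr_insertions):
        rng = _feature_rng(seed, spec.name, fidx)
        fidx += 1
        elem, i5_end, i3_start = _ltr_element(ltr, spec.mutation_rate_r, spec.gc, rng)
        eid = f"{spec.name}_LTR{k}"
        place(ltr.position, elem, eid)
        iv = GenomicInterval(spec.name, ltr.position, ltr.position + len(elem), "+")
        truth.tes.append((iv, ltr.family))
        truth.ltr_pairs[eid] = (
            GenomicInterval(spec.name, ltr.position, ltr.position + i5_end, "+"),
            GenomicInterval(
                spec.name, ltr.position + i3_start, ltr.position + len(elem), "+"
            ),
        )
        truth.ltr_ages[eid] = ltr.age_years

    for k, line in enumerate(spec.line_insertions):
        rng = _feature_rng(seed, spec.name, fidx)
        fidx += 1
        piece = random_dna(line.length, rng, spec.gc)
        place(line.position, piece, f"{spec.name}_LINE{k}")
        truth.tes.append(
            (
                GenomicInterval(spec.name, line.position, line.position + line.length, "+"),
                "LINE",
            )
        )

    return SequenceRecord(spec.name, seq.tobytes().decode()), truth


# ---------------------------------------------------------------------------
# Enrichment tracks


def simulate_enrichment_tracks(
    chrom_length: int,
    centromere: GenomicInterval,
    fold: float,
    mean_depth: float,
    bin_size: int,
    seed: int,
    chrom: str = "chr1",
) -> tuple[BinnedTrack, BinnedTrack]:
    """Poisson count tracks: Input ~ Poisson(depth) everywhere; CUT&Tag ~
    Poisson(fold*depth) in bins whose midpoint lies inside the centromere."""
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if centromere.end > chrom_length or centromere.start < 0:
        raise ValueError("centromere outside chromosome")
    rng = np.random.default_rng(seed)
    nb = n_bins(chrom_length, bin_size)
    mids = np.arange(nb) * bin_size + bin_size / 2
    lam = np.full(nb, float(mean_depth))
    lam[(mids >= centromere.start) & (mids < centromere.end)] *= fold
    cut = rng.poisson(lam).astype(float)
    inp = rng.poisson(np.full(nb, mean_depth)).astype(float)
    return (
        BinnedTrack(chrom, bin_size, cut, "raw", chrom_length),
        BinnedTrack(chrom, bin_size, inp, "raw", chrom_length),
    )


# ---------------------------------------------------------------------------
# GFF3 export of planted TEs


def truth_to_te_gff3(truth: TruthTable) -> pd.DataFrame:
    """Planted TE truth as a GFF3-shaped DataFrame (0-based internally).

    Intact LTR elements get child long_terminal_repeat features so the dating
    stage can extract the 5' and 3' repeats.
    """
    rows = []
    lidx = 0
    for iv, family in truth.tes:
        if family == "LINE":
            rows.append(
                dict(chrom=iv.chrom, start=iv.start, end=iv.end, strand=iv.strand,
                     type="LINE_element", id=f"{iv.chrom}_LINEx{lidx}", parent="",
                     family="LINE")
            )
            lidx += 1
    for eid, (l5, l3) in truth.ltr_pairs.items():
        family = next(f for iv, f in truth.tes if iv.start == l5.start and iv.chrom == l5.chrom)
        rows.append(
            dict(chrom=l5.chrom, start=l5.start, end=l3.end, strand="+",
                 type="LTR_retrotransposon", id=eid, parent="", family=family)
        )
        rows.append(
            dict(chrom=l5.chrom, start=l5.start, end=l5.end, strand="+",
                 type="long_terminal_repeat", id=f"{eid}_ltr5", parent=eid, family=family)
        )
        rows.append(
            dict(chrom=l3.chrom, start=l3.start, end=l3.end, strand="+",
                 type="long_terminal_repeat", id=f"{eid}_ltr3", parent=eid, family=family)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "type", "id", "parent", "family"],
    )
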