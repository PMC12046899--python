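"""Shared genomic data model and readers/writers.

All internal coordinates are 0-based half-open. BED and bedGraph are read and
written 0-based; GFF3 is read 1-based inclusive and converted on load.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N} (uppercase)."""

    id: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class BinnedTrack:
    """Fixed-bin per-chromosome numeric track.

    ``values`` has ``ceil(chrom_length / bin_size)`` entries; the last bin may
    cover a partial tail. ``norm`` is one of {"raw", "BPM", "ratio"}.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    norm: str = "raw"
    chrom_length: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.norm not in ("raw", "BPM", "ratio"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")
        if np.any(self.values < 0):
            raise ValueError("track values must be non-negative")
        if self.chrom_length is None:
            self.chrom_length = len(self.values) * self.bin_size
        expected = n_bins(self.chrom_length, self.bin_size)
        if len(self.values) != expected:
            raise ValueError(
                f"{self.chrom}: expected {expected} bins for length "
                f"{self.chrom_length} at bin size {self.bin_size}, got {len(self.values)}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.values)


def n_bins(chrom_length: int, bin_size: int) -> int:
    return math.ceil(chrom_length / bin_size)


@dataclass
class PipelineConfig:
    """Analysis constants, all exposed as attributes.

    ``min_monomer_len`` and ``min_copies`` are strict lower bounds for the
    tandem-array retention rule; ``cen_fold`` multiplies the per-chromosome
    mean ratio to define candidate centromere bins; ``mutation_rate_r`` is the
    neutral substitution rate (substitutions/site/year) used in LTR dating.
    """

    min_monomer_len: int = 50
    min_copies: int = 50
    hor_min_block: int = 2
    hor_max_div: float = 5.0
    cen_bin: int = 500
    cen_merge_gap: int = 100_000
    cen_fold: float = 2.0
    min_cen_len: int = 10_000
    cluster_ratio_threshold: float = 2.0
    rdna_min_cov: float = 0.90
    telomere_motif: str = "TTTAGGG"
    telomere_min_copies: int = 10
    telomere_distal_window: int = 20_000
    mutation_rate_r: float = 2.5e-9
    scan_window: int = 5_000
    scan_step: int = 2_500
    kmer_len: int = 12
    ratio_pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "min_monomer_len", "min_copies", "hor_min_block", "hor_max_div",
            "cen_bin", "cen_merge_gap", "cen_fold", "min_cen_len",
            "cluster_ratio_threshold", "rdna_min_cov", "mutation_rate_r",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# FASTA

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_genome(path) -> list[SequenceRecord]:
    """Load a (plain or gzipped) FASTA into SequenceRecords.

    Sequences are uppercased; duplicate IDs and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write rows of (GenomicInterval, name[, score]) as BED4/BED6."""
    with open(path, "w") as fh:
        for row in intervals:
            iv, name = row[0], row[1]
            fields = [iv.chrom, str(iv.start), str(iv.end), str(name)]
            if len(row) > 2:
                fields += [str(row[2]), iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            name = f[3] if len(f) >= 4 else "."
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


# ---------------------------------------------------------------------------
# bedGraph

def load_track(path, bin_size: int, chrom_lengths: dict[str, int]) -> dict[str, BinnedTrack]:
    """Rebin a bedGraph into fixed bins by length-weighted averaging.

    Uncovered bases count as 0 (they dilute the bin mean); intervals past the
    chromosome end or with negative values are errors.
    """
    sums = {
        c: np.zeros(n_bins(length, bin_size)) for c, length in chrom_lengths.items()
    }
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split()[:4]
            s, e, v = int(s), int(e), float(v)
            if chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome {chrom!r} in {path}")
            if e > chrom_lengths[chrom]:
                raise ValueError(
                    f"interval {chrom}:{s}-{e} exceeds chromosome length "
                    f"{chrom_lengths[chrom]}"
                )
            if v < 0:
                raise ValueError(f"negative value {v} at {chrom}:{s}-{e}")
            first, last = s // bin_size, (e - 1) // bin_size
            for b in range(first, last + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                sums[chrom][b] += v * (hi - lo)
    tracks = {}
    for chrom, arr in sums.items():
        length = chrom_lengths[chrom]
        widths = np.full(len(arr), float(bin_size))
        if length % bin_size:
            widths[-1] = length % bin_size
        tracks[chrom] = BinnedTrack(chrom, bin_size, arr / widths, "raw", length)
    return tracks


def write_bedgraph(tracks: dict[str, BinnedTrack], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for i, v in enumerate(t.values):
                start = i * t.bin_size
                end = min(start + t.bin_size, t.chrom_length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GFF3 (TE annotations)

def read_te_gff3(path) -> pd.DataFrame:
    """Read TE annotations from GFF3 into a DataFrame.

    Returns columns (chrom, start, end, strand, type, id, parent, family),
    coordinates converted to 0-based half-open. The ``family`` attribute
    carries CRM/ATHILA/LINE/other; intact LTR elements have child features of
    type long_terminal_repeat for the 5' and 3' repeats.
    """
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6] if f[6] in "+-" else ".",
                    "type": f[2],
                    "id": attrs.get("ID", ""),
                    "parent": attrs.get("Parent", ""),
                    "family": attrs.get("family", "other"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "type", "id", "parent", "family"],
    )


def write_te_gff3(df: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_te_gff3` (coordinates back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in df.iterrows():
            attrs = [f"ID={r['id']}"]
            if r.get("parent"):
                attrs.append(f"Parent={r['parent']}")
            if r.get("family"):
                attrs.append(f"family={r['family']}")
            fh.write(
                "\t".join(
                    [
                        r["chrom"], "cenland", r["type"], str(r["start"] + 1),
                        str(r["end"]), ".", r["strand"] or ".", ".", ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_anchor_pairs(path) -> pd.DataFrame:
    """Anchor TSV: pair_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "pair_id": str, "chrom_a": str, "chrom_b": str,
            "start_a": int, "end_a": int, "start_b": int, "end_b": int,
        },
    )
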