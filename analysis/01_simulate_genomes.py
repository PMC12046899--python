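#!/usr/bin/env python
"""Simulate the study's synthetic assembly with planted truth.

Builds a three-chromosome genome that carries the features the downstream
analyses target: a centromeric 156-bp satellite array (chr01), an array-free
centromere (chr02), a non-centromeric satellite subfamily (chr02), a 107-bp
satellite plus a 5S-like rDNA array (chr03), telomere runs, dated CRM/ATHILA
LTR insertions inside and outside centromeres, LINE insertions, and Poisson
CUT&Tag/Input tracks with 5-fold CENH3 enrichment over each planted
centromere. Writes FASTA, truth BED files, bedGraph tracks, a TE GFF3 and a
JSON manifest under results/data/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cenland.core_io import (
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_te_gff3,
)
from cenland.synthetic_data import (
    ChromosomeSpec,
    LTRInsertionSpec,
    LineInsertionSpec,
    SatelliteSpec,
    mutate,
    random_dna,
    simulate_chromosome,
    simulate_enrichment_tracks,
    truth_to_te_gff3,
)

OUT = Path("results/data")


def build_specs(seed):
    rng = np.random.default_rng(seed)
    cons156 = random_dna(156, rng)
    cons156_sub = mutate(cons156, 0.05, rng)  # chr02 subfamily of the same family
    cons107 = random_dna(107, rng)
    rdna_unit = random_dna(500, rng)

    chr01 = ChromosomeSpec(
        "chr01",
        2_000_000,
        telomeres="both_ends",
        satellites=[(900_000, SatelliteSpec(cons156, copies=500,
                                            per_base_divergence=0.02))],
        ltr_insertions=[
            # young centromeric CRMs
            LTRInsertionSpec(1_000_000, "CRM", 1_000, 3_000, 0.5e6),
            LTRInsertionSpec(1_010_000, "CRM", 1_000, 3_000, 1.0e6),
            LTRInsertionSpec(1_020_000, "CRM", 1_000, 3_000, 1.5e6),
            LTRInsertionSpec(1_100_000, "ATHILA", 1_500, 4_000, 2.0e6),
            # old chromosome-arm elements
            LTRInsertionSpec(200_000, "CRM", 1_000, 3_000, 6.0e6),
            LTRInsertionSpec(300_000, "ATHILA", 1_500, 4_000, 7.0e6),
            LTRInsertionSpec(1_700_000, "CRM", 1_000, 3_000, 8.0e6),
        ],
        line_insertions=[LineInsertionSpec(1_150_000, 5_000),
                         LineInsertionSpec(500_000, 5_000)],
        centromere=GenomicInterval("chr01", 750_000, 1_250_000),
    )
    chr02 = ChromosomeSpec(
        "chr02",
        1_400_000,
        telomeres="both_ends",
        satellites=[(200_000, SatelliteSpec(cons156_sub, copies=200,
                                            per_base_divergence=0.02))],
        ltr_insertions=[
            LTRInsertionSpec(820_000, "CRM", 1_000, 3_000, 0.8e6),
            LTRInsertionSpec(860_000, "ATHILA", 1_500, 4_000, 1.2e6),
            LTRInsertionSpec(1_200_000, "CRM", 1_000, 3_000, 5.0e6),
        ],
        line_insertions=[LineInsertionSpec(900_000, 5_000)],
        centromere=GenomicInterval("chr02", 800_000, 1_000_000),  # array-free
    )
    chr03 = ChromosomeSpec(
        "chr03",
        1_000_000,
        telomeres="one_end",
        satellites=[(300_000, SatelliteSpec(cons107, copies=150,
                                            per_base_divergence=0.03))],
        ltr_insertions=[LTRInsertionSpec(450_000, "CRM", 1_000, 3_000, 3.0e6)],
        centromere=GenomicInterval("chr03", 280_000, 480_000),
    )
    # rDNA array: 30 tandem exact copies planted directly on chr03
    return [chr01, chr02, chr03], dict(
        cons156=cons156, cons156_sub=cons156_sub, cons107=cons107,
        rdna_unit=rdna_unit,
    )


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    specs, seqs = build_specs(args.seed)
    records, truths = [], {}
    for spec in specs:
        rec, truth = simulate_chromosome(spec, args.seed)
        records.append(rec)
        truths[spec.name] = truth

    # splice the rDNA array into chr03 outside other features
    rdna_start = 600_000
    rdna = seqs["rdna_unit"] * 30
    c3 = records[2]
    records[2] = type(c3)(c3.id, c3.seq[:rdna_start] + rdna
                          + c3.seq[rdna_start + len(rdna):])

    write_fasta(records, OUT / "genome.fa")
    with open(OUT / "rdna_unit.fa", "w") as fh:
        fh.write(">rdna_5S_unit\n" + seqs["rdna_unit"] + "\n")

    truth_rows = {"arrays": [], "monomers": [], "telomeres": [], "cen": []}
    te_frames = []
    for name, truth in truths.items():
        truth_rows["arrays"] += [(iv, lab) for iv, lab in truth.arrays]
        truth_rows["monomers"] += [(iv, lab) for iv, lab in truth.monomers]
        truth_rows["telomeres"] += [(iv, lab) for iv, lab in truth.telomeres]
        if truth.centromere:
            truth_rows["cen"].append((truth.centromere, name))
        te_frames.append(truth_to_te_gff3(truth))
    for key, rows in truth_rows.items():
        write_bed(rows, OUT / f"truth.{key}.bed")
    import pandas as pd

    write_te_gff3(pd.concat(te_frames, ignore_index=True), OUT / "tes.gff3")

    cut_tracks, input_tracks = {}, {}
    for i, spec in enumerate(specs):
        cut, inp = simulate_enrichment_tracks(
            spec.length, spec.centromere, fold=5, mean_depth=50, bin_size=500,
            seed=args.seed + 100 + i, chrom=spec.name,
        )
        cut_tracks[spec.name], input_tracks[spec.name] = cut, inp
    write_bedgraph(cut_tracks, OUT / "cutandtag.bedgraph")
    write_bedgraph(input_tracks, OUT / "input.bedgraph")

    manifest = {
        "seed": args.seed,
        "chrom_lengths": {s.name: s.length for s in specs},
        "centromeres": {s.name: [s.centromere.start, s.centromere.end] for s in specs},
        "ltr_ages": {k: v for t in truths.values() for k, v in t.ltr_ages.items()},
        "rdna": {"chrom": "chr03", "start": rdna_start, "units": 30, "unit_len": 500},
        "satellite_families": {
            "chr01": {"consensus": seqs["cons156"], "copies": 500, "period": 156},
            "chr02": {"consensus": seqs["cons156_sub"], "copies": 200, "period": 156},
            "chr03": {"consensus": seqs["cons107"], "copies": 150, "period": 107},
        },
    }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))

    n_te = sum(len(t.tes) for t in truths.values())
    n_telo = sum(len(t.telomeres) for t in truths.values())
    print(f"Simulated {len(records)} chromosomes "
          f"({sum(r.length for r in records) / 1e6:.1f} Mb total) into {OUT}/")
    print(f"  planted: 3 satellite arrays, {n_te} TEs "
          f"({len(manifest['ltr_ages'])} dated LTR pairs), {n_telo} telomere runs, "
          f"1 rDNA array, 3 centromeres with 5x CUT&Tag enrichment")


if __name__ == "__main__":
    main()
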