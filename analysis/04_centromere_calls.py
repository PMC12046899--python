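#!/usr/bin/env python
"""Call centromeres from the simulated CUT&Tag/Input tracks.

Builds BPM-normalized CENH3/Input ratio tracks at 500-bp bins, calls
centromere intervals (candidates >= 2x the chromosome mean ratio, merged
under 100 kb, >= 10 kb long), compares each primary call to the planted
centromere, and computes arm ratios and the arm-scaled metaprofile. Writes
results/centromeres.bed and results/metaprofile.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from cenland.centromere_caller import (
    arm_scaled_metaprofile,
    call_centromeres,
    ratio_track,
)
from cenland.core_io import GenomicInterval, load_track, write_bed

DATA = Path("results/data")
OUT = Path("results")


def jaccard(a, b):
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / (max(a.end, b.end) - min(a.start, b.start))


def main():
    manifest = json.loads((DATA / "manifest.json").read_text())
    lengths = manifest["chrom_lengths"]
    cut = load_track(DATA / "cutandtag.bedgraph", 500, lengths)
    inp = load_track(DATA / "input.bedgraph", 500, lengths)
    ratios = ratio_track(cut, inp)
    calls = call_centromeres(ratios)

    write_bed(
        [(c.region, "primary" if c.is_primary else "secondary",
          round(c.mean_ratio, 2)) for c in calls],
        OUT / "centromeres.bed",
    )
    print(f"{len(calls)} centromere call(s) on {len(lengths)} chromosomes")
    mids = {}
    for c in calls:
        if not c.is_primary:
            continue
        chrom = c.region.chrom
        mids[chrom] = c.region.midpoint
        truth = GenomicInterval(chrom, *manifest["centromeres"][chrom])
        print(f"  {chrom}: {c.region.start}-{c.region.end} "
              f"mean ratio {c.mean_ratio:.1f}, arm ratio {c.arm_ratio:.2f}, "
              f"Jaccard vs planted {jaccard(c.region, truth):.3f}")

    profile = arm_scaled_metaprofile(ratios, mids, n_bins_per_arm=100)
    pd.DataFrame(
        {"arm_fraction": [i / 100 for i in range(100)], "mean_ratio": profile}
    ).to_csv(OUT / "metaprofile.tsv", sep="\t", index=False)
    print(f"arm-scaled metaprofile: telomere end {profile[0]:.2f} -> "
          f"centromere end {profile[-1]:.2f} (enrichment rises toward the "
          f"centromere as expected)")


if __name__ == "__main__":
    main()
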