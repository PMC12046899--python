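#!/usr/bin/env python
"""Date intact LTR retrotransposons and profile centromere TE composition.

Extracts the 5'/3' repeats of every intact element in the TE annotation,
computes identity, divergence K (K80) and insertion time T = K/(2r) with
r = 2.5e-9 substitutions/site/year, assigns centromeric vs non-centromeric
compartments from the called centromeres, compares the two compartments'
insertion times (Wilcoxon rank-sum) and tabulates per-centromere TE family
composition. Writes results/ltr_report.tsv and results/composition.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from cenland.core_io import GenomicInterval, load_genome, read_bed, read_te_gff3
from cenland.te_dating import (
    LTRElement,
    assign_compartment,
    centromere_composition,
    date_element,
    wilcoxon_rank_sum,
)

DATA = Path("results/data")
OUT = Path("results")


def main():
    genome = {r.id: r.seq for r in load_genome(DATA / "genome.fa")}
    manifest = json.loads((DATA / "manifest.json").read_text())
    tes = read_te_gff3(DATA / "tes.gff3")
    cen_calls = [iv for iv, _ in read_bed(OUT / "centromeres.bed")]

    elements = []
    for _, row in tes[tes["type"] == "LTR_retrotransposon"].iterrows():
        ltrs = tes[(tes["parent"] == row["id"])].sort_values("start")
        e = LTRElement(
            element=GenomicInterval(row["chrom"], row["start"], row["end"], "+"),
            family=row["family"],
            ltr5=GenomicInterval(*ltrs.iloc[0][["chrom", "start", "end"]]),
            ltr3=GenomicInterval(*ltrs.iloc[1][["chrom", "start", "end"]]),
            element_id=row["id"],
        )
        date_element(e, genome, model="K80")
        elements.append(e)
    assign_compartment(elements, cen_calls)

    rows = []
    for e in elements:
        planted = manifest["ltr_ages"].get(e.element_id)
        rows.append([e.element_id, e.family, round(e.identity, 2),
                     round(e.K, 5), round(e.T / 1e6, 3),
                     planted / 1e6 if planted else None, e.compartment])
    df = pd.DataFrame(rows, columns=["element", "family", "identity_pct", "K",
                                     "T_mya", "planted_mya", "compartment"])
    df.to_csv(OUT / "ltr_report.tsv", sep="\t", index=False)

    cen_t = df[df["compartment"] == "centromeric"]["T_mya"]
    arm_t = df[df["compartment"] == "non_centromeric"]["T_mya"]
    stat, p = wilcoxon_rank_sum(list(cen_t), list(arm_t))
    print(f"{len(df)} intact LTR elements dated "
          f"(median centromeric {cen_t.median():.2f} Mya vs "
          f"non-centromeric {arm_t.median():.2f} Mya; Wilcoxon p = {p:.3g})")
    err = (df["T_mya"] - df["planted_mya"]).abs() / df["planted_mya"]
    print(f"mean per-element |estimated - planted| / planted = {err.mean():.1%} "
          f"(sampling noise on a few substitutions dominates for 1-kb repeats)")

    line_rows = [
        (GenomicInterval(r["chrom"], r["start"], r["end"]), r["family"])
        for _, r in tes[tes["parent"] == ""].iterrows()
    ]
    reports = centromere_composition(line_rows, cen_calls)
    comp_rows = []
    for rep in reports:
        comp_rows.append(
            [rep.centromere.chrom, rep.centromere.start, rep.centromere.end,
             round(rep.family_percent["CRM"], 2),
             round(rep.family_percent["ATHILA"], 2),
             round(rep.family_percent["LINE"], 2),
             round(rep.repeat_percent, 2)]
        )
    comp = pd.DataFrame(comp_rows, columns=["chrom", "start", "end", "CRM_pct",
                                            "ATHILA_pct", "LINE_pct", "TE_pct"])
    comp.to_csv(OUT / "composition.tsv", sep="\t", index=False)
    print("centromere TE composition (%):")
    print(comp.to_string(index=False))


if __name__ == "__main__":
    main()
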