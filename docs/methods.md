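# Methods

`cenland` re-implements, as a tested pipeline over synthetic genomes with
planted truth, the sequence analyses used to characterize centromere
landscapes in Salicaceae (poplar and willow) assemblies: tandem repeat array
(TRA) discovery and higher-order repeat (HOR) decomposition, satellite
variant-distance statistics, CENH3 CUT&Tag enrichment-ratio centromere
calling, LTR retrotransposon insertion-time dating, centromeric TE
composition, telomere and rDNA detection, and centromere repositioning
classification. This note records the models, the parameters that matter,
and the places where the design was genuinely open.

## Coordinate conventions

All internal coordinates are 0-based half-open. BED and bedGraph files are
read and written 0-based; GFF3 is 1-based inclusive on disk and converted on
load. `N` bases are legal in genomes and never match any motif or k-mer.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

* **Satellite arrays.** An array is `copies` concatenated monomers, each the
  consensus with i.i.d. substitutions at `per_base_divergence` (a
  substitution always changes the base). With HOR structure, a block of
  `unit_size` distinct variant monomers (drawn once at `variant_divergence`,
  default 5%) is tandemly repeated `unit_repeats` times before the
  independent per-copy mutation. The mutation model is substitution-only by
  default so truth coordinates stay exact; a per-monomer 1-bp indel rate can
  be enabled to exercise gap handling.
* **LTR elements.** An insertion of age `A` emits 5'LTR–internal–3'LTR where
  the two LTRs start identical and each receives i.i.d. substitutions at
  `r·A` (r = 2.5×10⁻⁹ substitutions/site/year), so their expected pairwise
  divergence is `2·r·A` — exactly the assumption of the dating formula.
  Because substitutions can coincide, the true expected mismatch fraction is
  `2q(1−q) + (2/3)q²` with `q = r·A`, a <1% downward bias at 5 Mya.
* **Telomeres.** Exact motif runs (default 100 copies of the 7-bp unit) at
  the chromosome ends, with the biological orientation: the 5' end carries
  the CCCTAAA run, the 3' end TTTAGGG.
* **Tracks.** Input bins ~ Poisson(depth); CUT&Tag bins ~ Poisson(depth)
  outside and Poisson(fold·depth) inside the planted centromere (bin
  membership by midpoint). Defaults used throughout the tests — fold 5,
  depth 50 reads per 500-bp bin — represent a well-powered CUT&Tag
  experiment.
* **Seeding.** One global seed expands into per-feature child streams keyed
  by (seed, CRC32 of chromosome name, feature index), so results do not
  depend on simulation order.

What the generator does **not** emulate: indel-rich satellite turnover,
segmental duplications, GC-heterogeneous background, mappability artifacts
in coverage tracks, or phylogenetically structured multi-species variation.
Passing tests therefore demonstrate correctness of the algorithms under the
stated generative model, not performance on arbitrary real assemblies.

## Tandem repeat discovery

Discovery is k-mer based (in the TRF/TRASH family of approaches, chosen for
implementability and testability against planted truth):

1. **Window period.** 5-kb windows (step 2.5 kb) are scored by the modal
   spacing between recurrences of repeated 12-mers; a window qualifies when
   >20% of positions start a repeated k-mer. Periods ≤ 2 are discarded
   (homopolymers, dinucleotide wobble).
2. **Region merging.** Adjacent qualifying windows with periods within 10%
   merge into candidate regions; the period is refined to the modal spacing
   of the region's most frequent k-mer (exact for substitution-only arrays).
3. **Edges.** Coarse edges come from self-matching at one period's distance;
   the precise edge is a two-segment change-point split of per-base
   agreement with the phased consensus, with log-likelihood weights (+1.4
   per agreement, −3.6 per disagreement, from ~97% in-array vs 25%
   background agreement). This is single-bp accurate and robust to point
   mutations near the array edge.
4. **Monomer cuts.** Occurrences of the anchor k-mer define cut points with
   no cumulative drift; the grid is phased to the refined array start and
   gaps (missed anchors) are filled at period multiples.
5. **Consensus and strand.** Per-column majority vote over the cut monomers.
   Strand is assigned from the rotation-minimal (circular) canonical form of
   the consensus versus its reverse complement — stable under monomer phase —
   and the consensus is reported in canonical orientation. Family labels are
   `<tag><canonical length>`, mirroring satellite naming like *Palv156*.

Monomer divergence is edit distance to the consensus divided by consensus
length (indel-tolerant). The retention rule keeps arrays with monomer length
strictly > 50 bp and copy number strictly > 50; copy number is counted per
array (whether the original rule counted per array or per family per
chromosome is ambiguous; per array is implemented).

## Higher-order repeats

The monomer-vs-monomer % divergence matrix (edit distance / period × 100) is
scanned along each diagonal offset `d ≥ 1` for maximal runs of consecutive
aligned pairs **each** within `maxdiv` (default 5%); runs of length ≥
`minhor` (default 2) become HOR blocks pairing monomers `[i, i+L)` with
`[i+d, i+d+L)`, with the block divergence reported as the mean over its
pairs. Building runs from a per-pair bound rather than a running mean keeps
maximality well-defined (a mean constraint is non-monotone under
extension); the distinction only matters for runs straddling a single
outlier pair. All maximal runs from all diagonals are reported — runs on
different diagonals describe different periodicities of the same
homogenized array and are not competitors — sorted by size then divergence.
A brute-force enumeration oracle in the test suite verifies the scan
exactly on matrices of ≤ 30 monomers.

## Satellite variant distance and identity

Monomers are aligned by a consensus-anchored star alignment: each monomer is
globally aligned to the consensus (match +1, mismatch −1, gap open −2, gap
extend −0.5), pairwise alignments are projected onto consensus columns, and
insertions relative to the consensus are appended as extra columns at their
host position (absent monomers carry gaps there). This replaces a de novo
MSA: it is deterministic, dependency-light, and adequate for per-column
proportion statistics; it will differ from an MSA when monomers share
insertions the consensus lacks.

For each column the proportions of A, C, G, T and gap are tabulated — gaps
count as a fifth element — and a monomer's variant distance at a column is
1 minus the proportion of its own element; distances are cumulated over all
columns. An option (`skip_gap_positions`) restricts a monomer's sum to its
non-gap columns, since either reading of "cumulated over all positions" is
defensible; the default counts every column.

Pairwise identity is matches / alignment columns of the global alignment
(gap columns count against identity), computed on the literal orientation —
no automatic reverse-complementing. Group comparisons split off-diagonal
identities into within- and between-group sets and report medians with a
two-sided Wilcoxon rank-sum p-value.

Representative monomers are the most frequent exact sequence per chromosome
(ties broken lexicographically). Proportional sampling uses
largest-remainder quotas so per-chromosome counts sum exactly to the target.

## Centromere calling

Raw tracks are BPM-normalized jointly across chromosomes (bin × 10⁶ / total)
and the enrichment ratio is `(cut + p) / (input + p)` per 500-bp bin with a
pseudocount of 1 BPM unit. Computing ratios at the working bin size directly
from BPM values, rather than at 1-bp resolution and re-binning, is
mathematically equivalent for count data up to pseudocount placement and far
cheaper.

Candidate bins have ratio ≥ `cen_fold` × the per-chromosome mean ratio.
The published procedure never states the candidate threshold (final calls
were inspected visually); the fold-over-mean rule with `cen_fold` = 2 —
consistent with the repeat-cluster binding rule's ratio > 2 — is this
package's operationalization and is exposed as a flag. Candidates separated
by < 100 kb merge; blocks shorter than `min_cen_len` (default 10 kb, small
enough to admit the smallest reported centromeres) are dropped; the block
maximizing Σ(ratio − chromosome mean) is the primary call per chromosome.

Arm ratio is long arm / short arm measured from the chromosome ends to the
centromere midpoint. Arm-scaled metaprofiles rescale every arm
(telomere → centromere midpoint) to a fixed number of equal fractions via
length-weighted means of the underlying bins and average over all arms.

Repeat-cluster binding uses the normalized CUT&Tag/Input count ratio with a
strict > 2 threshold and a 1-read pseudocount for empty input clusters.

## LTR dating

Identity between a pair of sequences is the percentage of identical pairs
over all alignment columns. Divergence K is computed over gap-free aligned
columns under raw (p-distance), JC69, or K80 (default, matching the common
dist.dna default for LTR dating); saturation (log argument ≤ 0) raises an
error rather than returning a silent NaN. Insertion time is T = K/(2r).

Alignment dispatch: equal-length pairs with ≤ 25% direct mismatches use the
ungapped column pairing (the optimal affine-penalty alignment for
high-identity equal-length pairs, and the generative alignment for the
simulator's data); short unequal pairs use the affine DP above; pairs beyond
10⁶ DP cells fall back to edlib's banded unit-cost global alignment. The
affine DP is quadratic and would dominate runtime on multi-kb repeats.

Elements are assigned to the centromeric compartment iff their midpoint
falls inside a called centromere — the unambiguous, symmetric choice when no
partial-overlap rule is stated. Composition reports credit each base to a
single family, resolving overlaps by longer-annotation priority before the
per-family union (nested TE annotations are common in EDTA-style output).

## Wilcoxon rank-sum

Midranks for ties; the two-sided p is by exact enumeration of all
C(n+m, n) assignments when n+m ≤ 16 (p = fraction of assignments whose
rank-sum deviates from its mean at least as much as observed), otherwise a
normal approximation with tie correction and a 0.5 continuity correction.
The exact path is verified against an independent exhaustive-permutation
oracle for all tie-free sizes with n+m ≤ 10.

## Telomeres and rDNA

Telomere scans cover a 20-kb distal window at each chromosome end (the
window is not specified by the original procedure and is configurable),
searching both TTTAGGG and CCCTAAA for maximal tandem runs in which each
unit has ≤ 1 mismatch and the total mismatched units stay within 1 per 10
copies (an exact-only mode exists); runs need ≥ 10 copies and only the
longest run per end is reported.

rDNA units are located by exact 15-mer seed matching grouped by diagonal; a
copy is retained when seeds cover ≥ 90% of the unit, which makes the
matcher conservative for diverged copies (a ~1% diverged 500-bp copy loses
enough seed coverage to fall below the threshold); copies closer than two
unit lengths merge into arrays.

## Repositioning

Cross-species read remapping is replaced, at desk scale, by reciprocal
anchor projection: the nearest homologous-gene anchors flanking a
centromere delimit its projected span between their partners' inner
coordinates, orientation-aware so inverted blocks project correctly. A pair
is *conserved* when either reciprocal projection overlaps the partner
centromere by ≥ 1 bp (projections are coarse, bounded by anchor density; a
reciprocal-overlap-fraction flag allows stricter calls), *repositioned*
when both projections resolve and are disjoint, *unresolved* otherwise.
The rule is symmetric under genome swap, and an inversion that carries the
centromere while preserving its syntenic neighborhood is classified
conserved — distinguishing inversion-carried from truly repositioned
centromeres.

## Problem sizes

The test suite and acceptance script run on: a 2-Mb chromosome with a
500-copy 156-bp array (discovery), 100 seeded replicates of 2-Mb tracks
(centromere recovery), 200 replicates per age of 5-kb LTR pairs at 0.5/1/5
Mya (dating), a 19-chromosome 150-kb-per-chromosome assembly (telomere
census), 1,000 random alignments ≤ 6×10 (variant-distance oracle) and 50
random divergence matrices ≤ 30 monomers (HOR oracle). The analysis drivers
use a 4.4-Mb three-chromosome assembly. These sizes give stable statistics
(binomial/CLT tolerances in the tests are sized to them) while keeping the
full pipeline fast on one CPU.

## Known limitations

* Discovery assumes arrays dominated by a single period; nested or mixed
  arrays merge into one region and take the modal period.
* Strand assignment is meaningful only relative to the circular canonical
  form of the consensus; for a palindrome-like consensus it is arbitrary.
* The star alignment under-counts shared insertions relative to an MSA.
* The rDNA matcher is exact-seed based and intentionally conservative for
  diverged copies.
* Reposition calls degrade gracefully to "unresolved" under sparse anchors;
  projection precision is bounded by anchor spacing.
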