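# Methods

## The duplex-formation model

The genome model is deliberately positional, not thermodynamic. A
`TranscriptionUnit` is an ordered exon chain on one strand with a poly(A)
site, a relative expression weight, one splicing efficiency per intron (the
probability that a given molecule has that intron removed), and a poly(A)
read-through probability. Coordinates are 0-based half-open everywhere in
memory; GTF/SAM conversion happens only at serialization.

The *pre-mRNA footprint* of a unit runs from its first exon start to its
poly(A) site, extended by a fixed `readthrough_length` (default 500 nt, a free
parameter — read-through frequency in this system is not quantified) for units
with nonzero read-through probability. A duplex-competent region is any
interval where a top-strand footprint overlaps a bottom-strand footprint:
complementary RNA can anneal there in *trans*. Each pair overlap is split at
the boundaries of both units' mature-mRNA footprints so that every emitted
region carries a single annotation:

* `klass`: `intron_exon` if the overlap exists for normally terminated
  pre-mRNAs, `polya_readthrough` if it exists only via the read-through
  extension of one side;
* `requires_unspliced`: which side contributes no mature (exonic) bases to the
  interval — i.e. splicing that side abolishes the duplex. On genomes whose
  exons never overlap antisense exons (both presets, and the real virus
  layout), every `intron_exon` region requires at least one unspliced side:
  the formal statement of "efficient splicing prevents dsRNA".

Correctness is checked against a per-base bitmask oracle (mark every base
covered by any top footprint and any bottom footprint; intersect) on both
presets and on 120+ random genomes.

The `ad5_like` preset mimics the adenovirus layout: early units (E1A-, E1B-,
E3-like) and a major-late family on the top strand — four isoforms sharing a
three-exon tripartite-leader with alternative 3' exons (L2–L5-like) — and
E2-/E4-like units transcribed right-to-left on the bottom strand. The genome
core is intron/exon duplex territory (late introns antisense to the E2 span);
the right end pairs only by read-through (fiber/E4), matching where the two
classes of potential dsRNA live in the real transcriptome.

## Library simulation

An input library draws `n_molecules` molecules per unit proportional to
expression weight; each intron is removed independently with its splicing
efficiency; read-through happens with the unit's probability; a `host_fraction`
(default 0.25) of molecules is emitted on a single synthetic decoy contig —
only the viral/host read fraction needs a second reference, so no real host
genome is modeled. Reads of fixed length (default 100 nt) pick a molecule
uniformly at random (among molecules at least one read long — shorter ones are
skipped with a logged warning), then a start uniform over valid windows. Each
read carries the strand of its transcript of origin (library prep is
abstracted as perfectly directional), alignment blocks projected to genome
coordinates with gaps at removed introns, and a uniform random fixed-length
UMI (default 8 nt; collisions are allowed and the deduplicator must tolerate
them). PCR-style duplicates are injected at `umi_dup_rate` (default 0.05).

Uniform-per-molecule sampling makes the expected viral read fraction equal the
viral molecule fraction, and gives the spliced-read estimator a closed form:
for a single-intron unit with efficiency *s*, spliced mapped length *L*s and
read length *L*, the probability a read carries the junction is
`s (L-1) / (Ls - L + 1)` — the oracle used in tests.

The IP step models single-strand-specific RNase digestion followed by
anti-dsRNA antibody capture. For each predicted duplex region, the *partner
availability* is the fraction of opposite-side molecules whose footprint
overlaps the interval (for intronic contributions this is the partner's
unspliced fraction there). A molecule overlapping a region anneals with
probability `duplex_formation_rate × availability` per region; the formation
rate (default 0.1) is the free proportionality constant of the engagement
model — annealing needs a molecular collision, so it is far below 1 even when
partners are abundant. Engaged molecules are captured with `ip_duplex_capture`
and trimmed to the fired interval(s) ± `rnase_overhang` (default 30 nt);
trimming emits one fragment per contiguous protected piece, because a
sequencing read cannot span an RNase cut — splice junctions survive only when
protected on both sides. All other molecules (including all host molecules)
are captured untrimmed at `ip_background_capture` (default 0.05), representing
nonspecific recovery. Engagement is monotone in intron retention by
construction: lowering any splicing efficiency can only increase both a
molecule's own overlap with duplex regions and its partners' availability.

Scenario ground truths: the wildtype-like condition uses splicing efficiency
0.95 everywhere and sets `ip_duplex_capture = ip_background_capture` (no
capture beyond background), so its IP is an unbiased subsample of the input
pool; the mutant-like condition uses efficiency 0.35 and duplex capture 0.8.
The default experiment is 2 conditions × 2 replicates × {input, IP} = 8
libraries at 100 000 reads and 40 000 molecules per library — sizes chosen so
that per-junction abundances of a background-rate IP are estimated from a few
thousand distinct molecules and the panel junctions are covered in every
library. Every stage is a deterministic function of
(seed, condition, replicate), with independent streams for the molecule pool
and the IP.

## RIP-seq quantification

* **Deduplication** collapses reads on the exact key (UMI, reference, strand,
  full block structure), keeping the lexicographically smallest read id. No
  edit-distance clustering: synthetic UMIs carry no sequencing errors, and a
  UMI-error mode is out of scope. The operation is idempotent and order-independent.
* **Junctions** are the inter-block gaps of deduplicated reads, keyed by
  (reference, strand, donor, acceptor) with no transcript-model annotation.
  Counts are normalized to reads per million unique mapped deduplicated reads
  of the library (the ×10⁶ scale cancels in every fold change).
* **Reproducibility filter**: a junction is real in a library with ≥ 2 unique
  reads (used per library for the global spliced-read percentage); the
  splicing-index panel keeps junctions meeting the threshold in *every*
  library. In synthetic mode the panel is all cross-library-reproducible viral
  junctions; in real mode a BED panel can be supplied.
* **Splicing index**: per junction and replicate,
  `log2((rpm_ip + c) / (rpm_input + c))` with pseudocount `c = 0.5` by default.
  The cross-library filter makes zeros impossible on the panel, so the
  pseudocount only guards misuse; with `c = 0` a zero abundance raises.
  Replicates are averaged per junction first, then condition mean/SD are taken
  across junctions, and conditions are compared by a two-sided rank-sum test
  on the per-junction values. Whether totals should count all mapped reads or
  viral-only is ambiguous in principle; the denominator here is all mapped
  deduplicated reads of the library.
* **Enrichment ratio** is the IP viral-read percentage over the matched input
  percentage (1 = no enrichment); it requires a nonzero input percentage.

The rank-sum test enumerates all C(n1+n2, n1) labelings exactly when both
groups have ≤ 8 observations (midranks handle ties; the two-sided p sums both
tails of the U distribution) and otherwise uses the tie-corrected normal
approximation with continuity correction via SciPy. The exact path is verified
against an independent enumeration oracle and against SciPy's exact method on
tie-free data.

## MNFI image quantification

Segmentation follows the standard FIJI-style recipe: estimate the smooth
background as a large-sigma Gaussian of the DAPI image (default sigma 50 px —
an approximation of rolling-ball background subtraction that is equivalent on
smooth synthetic backgrounds), subtract and clip at zero, blur (sigma 2 px),
threshold by Otsu's method (the thresholding method is otherwise unspecified;
a manual threshold can be passed around the function), label 8-connected
components, and drop objects under `min_area` (default 100 px) or touching the
border. Touching nuclei are not split (synthetic fields are non-touching by
construction; clumped real nuclei are a documented limitation). Background
subtraction and Otsu make the result invariant to a constant intensity offset.

Per-nucleus area, min, max, and mean intensity under the mask applied to the
dsRNA channel give the MNFI. A nucleus is dsRNA-positive when its MNFI
*strictly* exceeds `control mean + k × control SD` (k = 4; sample SD with n−1
denominator, so ≥ 2 control nuclei are required). Condition summaries report
n cells, % positive, and the mean/SD of MNFI among positive nuclei, plus
pairwise rank-sum tests on the full MNFI distributions.

The image simulator places non-touching disks (bounded rejection sampling;
failure raises) with a constant dsRNA baseline plus Gaussian noise, adding a
fixed `mean_shift` inside positive nuclei. The number of positives is the
exact rounded count `round(frac_positive × n_cells)`, assigned at random, so
classifier recovery is scored against the configured fraction without extra
composition noise. What passing these tests does *not* show: robustness to
uneven illumination, clumped or apoptotic nuclei, out-of-focus fields, or
antibody-specific staining patterns.

## qPCR statistics

Amplification efficiency is fixed at 2 per cycle (standard ΔΔCt; no standard
curves). Technical replicates are averaged on the Ct scale, then samples per
condition. ΔCt subtracts the mean of the reference genes; ΔΔCt subtracts the
calibrator condition; relative expression is `2^(−ΔΔCt)`, so the calibrator
reports 1 and the result is invariant to per-sample Ct offsets. Splicing
efficiency is the spliced/unspliced relative-expression ratio (the common
calibrator cancels). Percent-of-input adjusts the input Ct by
`−log2(1/input_fraction)` (default 1% input; the adjustment is on by default
and switchable via `input_fraction=1`), reports
`100 × 2^(adjusted_input − ct_ip)`, and calls a target positive when it
strictly exceeds twice the mean of the negative-control percentages. The Ct
simulator draws `Ct = base_ct − log2(abundance) + N(0, noise_sd)`, which makes
a 2× template exactly one cycle earlier at zero noise and retains ground-truth
fold changes.

## Numerical and design choices

* Strand convention: a read's strand equals its transcript-of-origin strand.
* Duplex engagement is interval-level; no hybridization thermodynamics, no
  sequence-level folding, no VA-RNA/PKR biology.
* Ties in dedup resolve to the smallest read id; positivity thresholds use
  strict inequality; boundary equality is negative.
* Degenerate inputs raise: empty libraries for viral fraction, zero input
  percentage for enrichment, fewer than two control nuclei, non-positive
  unspliced expression, out-of-range input fractions.
* All simulators are bit-for-bit reproducible given a seed; artifact files
  (SAM/GTF/BED/TSV/JSON) are byte-identical across runs with the same config.

## Known limitations

The simulators emulate the statistical structure of the assays, not their
chemistry: no sequencing errors or UMI errors, no coverage bias, no rRNA or
library-chemistry effects, single-isoform units (alternative splicing is
represented as separate units sharing exons), a single decoy host contig, and
2-D non-touching nuclei. Results on synthetic data demonstrate correctness of
the estimators under the stated generative model, not performance on any
particular real dataset.
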