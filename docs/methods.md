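# Methods

`silencer-scope` re-implements, as a reusable and tested pipeline, the
computational analysis used to characterise the genome-wide targetome of a
zinc-finger xenogeneic silencer (MucR/Ros family) in a multipartite
α-proteobacterial genome. This note documents the models and procedures,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where conventions were open.

## Peak consolidation and target assignment (`peaks`)

Peaks called per condition (free-living cells, FC; bacteroid cells, BC) and
replicate are consolidated by **single-linkage clustering of summit
positions**: two peaks on the same replicon are linked when their summits
are closer than 200 bp (strictly below the threshold), and linkage is
transitive. The published rule is stated pairwise ("summits closer than
200 bp get the same peak id"); transitive chaining is its minimal
deterministic closure. Records are canonically sorted by (replicon, summit,
condition, replicate) before clustering, so the result is independent of
input order. The consensus summit is the median member summit, taking the
smaller of the two middle values for even member counts. Per-condition
enrichment of a merged peak is the maximum member fold for that condition —
a conservative recovery of the strongest signal; when the input table
already carries combined per-condition folds, the maximum is a no-op.

A merged peak is *shared* when members from both conditions are present,
otherwise *FC_only*/*BC_only*. Condition-specific peaks are additionally
counted against a low-fold threshold (default 5), since condition-specific
binding is characteristically weak.

A gene is a **target** when a consensus summit lies in its regulation
window: `[start − 500, start + 100]` around the start codon,
strand-oriented and inclusive on both ends (inclusivity is the common
annotation convention; both bounds are configurable). A peak may target
several genes (divergent promoters) and a gene may carry several peaks.
Windows running past position 1 are truncated; no circular wrap-around is
applied by default because plasmid FASTA files are linearised. Operons are
deliberately not expanded: only the peak-proximal gene counts, which makes
target counts conservative.

Sequence features of a peak are computed on its **200-bp central region**
`[summit − 99, summit + 100]`; windows truncated at replicon ends are
returned shorter and flagged.

## Flexible-pattern scanner (`flexmotif`)

The binding signature is a degenerate pattern of T/G literals with
periodic repeats of Ts roughly one helical turn apart:
`TT xxx G xxx T xxxxxxxxxx TT` — literal blocks `TT, G, T, TT` separated by
non-conserved gaps of nominal lengths 3, 3 and 10 bp. Indel tolerance is
**per gap**: gaps 1 and 2 may each shrink or grow by one base, gap 3 by two
(reading the parallel phrasing "no more than one … in the first two regions
and no more than two … in the third" as independent per-region budgets; a
shared-budget alternative is expressible through `gap_tolerances`). The
default span range is therefore 18–26 bp.

The scanner reports **every start position per strand** at which at least
one gap assignment spells the literals, recording the lexicographically
smallest feasible gap realisation — one match per (start, strand), so
counts mean "number of match start sites" and combinatorial double counting
cannot occur. Matches may overlap. Minus-strand matches are found on the
reverse complement and reported in forward-axis coordinates; note the
stable anchor of a minus-strand match is its forward-axis *end* (the
pattern start on the scanned strand). Internally the scan is a conjunction
of shifted base-equality arrays per gap combination (45 combinations for
the default spec), which matches an exhaustive enumeration oracle exactly
and runs in linear time.

Genome-wide scans use both strands (the pattern is non-palindromic);
gene-relative distance analyses use the coding strand, since promoter
analyses are inherently oriented.

**Motif–gene distances** are motif midpoint minus the first nucleotide of
the gene, strand-oriented (positive = into the coding region), retained in
[−500, +2000]; for genes shorter than 2000 bp, positive distances beyond
the stop codon are dropped so downstream intergenic sequence never
contaminates the intragenic signal. Midpoints of even-span matches are
half-integers and are compared without rounding. Positional summaries are
Gaussian kernel densities (Silverman bandwidth unless overridden),
renormalised over the analysis grid so the curve is a proper density on
[−500, +2000].

## Composition statistics (`composition`)

AT% is `100·(A+T)/(A+C+G+T)` over unambiguous bases — N counts toward
neither numerator nor denominator, so assembly gaps do not bias
composition.

**Oligonucleotide usage deviation** removes mononucleotide bias with a
zero-order Markov expectation: for a word W of length k in a region of
length L, `expected(W) = (L−k+1)·Π f(W_i)` where f are the region's own
base frequencies, and `deviation = observed/expected` with overlapping,
non-circular window counts. Per-region (not pooled) normalisation is used
for peak regions, genome-wide frequencies for the genome-wide table; the
choice is exposed. Both observed and expected sum to L−k+1. A word using a
base absent from the region has expected 0 and its deviation is reported
missing (NaN).

**Binding preference** of a word is Spearman's rho (average ranks for
ties) between the per-peak deviation of that word and the peak's
enrichment fold, with pairwise exclusion of missing deviations.
Benjamini–Hochberg adjustment across the 4^k words is available but off by
default (raw rho/p are the primary report). The preference–genome relation
is an ordinary least-squares regression of rho on genome-wide deviation
across words, summarised by R².

**Recruitment correlations** are Pearson correlations of enrichment fold
with region AT% and with flexible-motif count, on raw peaks and optionally
on fold-bin means (default edges 1, 2, 5, 10, ∞ — matching the fold-5
peak-class cut used elsewhere; the published bin edges are not stated).

## Promoter models (`promoters`)

Per sigma factor (RpoD, RpoH1, RpoH2, RpoE2, RpoN) separate −35 and −10
**position-specific scoring matrices** are built from aligned training
sites: column probability `(count + 0.5)/(n + 2)`, score
`log2(probability/background)`. Genome scanning slides both strands and
pairs every above-threshold −35 hit with every downstream −10 hit whose
spacer length lies in the sigma factor's allowed range; all overlapping
pairs are reported because downstream statistics are per hit. Score
thresholds default to the 90th percentile of the training sites' own
scores — a self-contained, reproducible rule standing in for the unstated
cutoffs of external profile-search tools. Spacer-length defaults (RpoD
15–19 bp; RpoN 4–6 bp between its −24/−12-style elements; others 14–20 bp)
are explicit configuration placeholders, not literature values.

A hit is **intragenic** when the 3′ end of its −10 element lies inside any
gene body on either strand, else intergenic; its associated gene is the
nearest downstream gene start on the hit strand within 500 bp (mirroring
the regulation-window upstream bound). Spacer AT% of hits associated with
target vs non-target genes is compared per (sigma, context) stratum with
Welch's t-test; strata with fewer than two hits in either group are
skipped.

## Pangenome conservation classes (`pangenome`)

Genes are classified from an ortholog-cluster table into four mutually
exclusive hierarchical subsets: **I** genus core (cluster spans all genus
strains), **II** species core (all species strains, excluding I), **III**
shared by the focal strain's closest relatives (excluding I–II), **IV**
strain-specific. Genes absent from the cluster table are strain-specific
by absence of orthologs and land in IV.

Target enrichment by replicon or subset uses two-sided Fisher exact tests
on 2×2 tables (in-stratum × target status), with Benjamini–Hochberg
adjusted p-values reported alongside raw ones. Gene AT% is computed over
the annotated coding span (strand-symmetric). Expression analysis is
descriptive only — per-(subset × target status × condition) summaries,
Welch t-tests of target vs non-target within subset, and a paired contrast
of target-gene expression between wild type and the silencer mutant;
differential-expression calling is consumed as an optional input, never
computed. The relation between conservation and recruitment is summarised
as the subset composition of target genes per enrichment-fold bin with a
Spearman trend test on the genus-core fraction.

## Synthetic data generator (`synthetic`)

The generator emulates the statistical structure the analysis assumes, at
about one third of the real genome's scale so that the default run
finishes in seconds: three replicons (chromosome 1 Mb GC 62%, chromid
0.7 Mb GC 61%, symbiosis plasmid 0.5 Mb GC 59%), ~1700 non-overlapping
genes of 0.6–1.5 kb, six 3-kb AT-rich islands per replicon (GC −18
points). Subset labels I–IV are allocated at exact proportions
(0.45/0.15/0.10/0.30) and island genes are swapped to IV (foreign genes
cluster in islands; the swap preserves counts). Gene sequence GC is offset
by subset (+2/0/−3/−9 points), giving the I < II < III < IV AT ordering.

The flexible motif is planted as concrete canonical-gap instances at
0.8/kb inside islands and 0.06/kb elsewhere; planted spans are protected
from later overwrites, so every plant is recoverable by the scanner.

500 ChIP peaks are placed: 60% in gene regulation windows with
subset-weighted gene choice (weights 0.6/0.9/1.2/2.4 for I–IV — the
silencer is drawn to AT-rich foreign genes), the rest at random positions;
summits are kept ≥400 bp apart so the planted peak set is identifiable
after merging. Enrichment fold follows

```
fold = max(1.01, −12 + 0.4·AT% + 2·motifs + 7·max(0, dev_TA − 1) + N(0, 2))
```

computed on the true 200-bp central region, where `dev_TA` is the region's
realised TpA usage deviation. TpA variance is created by planting up to 25
TA steps per region with an intensity z ∈ [0,1]; the planted count scales
with the region's expected TA count (∝ AT%²) so the deviation gain is
composition-neutral and the TpA preference is not a disguised AT effect.
64.6% of peaks are shared between conditions (each condition's record gets
a small lognormal fold jitter and ≤30 bp summit jitter); condition-specific
peaks are attenuated ×0.25, leaving the large majority below fold 5.

Expression is lognormal with subset-decreasing means (100/70/50/30 in
arbitrary normalised units, σ_log = 0.7), a ×1.6 multiplicative boost for
target genes and a further ×1.8 up-shift of targets in the mutant
condition. Promoter training sets are consensus −35/−10 sites mutated at
rate 0.12; 200 consensus element pairs with 17-bp spacers are planted
upstream of genes — spacers of target-associated promoters at 72% AT,
non-target at 64% (the +8-point shift the pipeline should detect). The
cluster table realises each subset's defining strain pattern over a
12-strain genus universe (5 species strains, 3 close strains), with 2% of
IV genes omitted from the table entirely.

All randomness flows from one `SeedSequence` spawned into named
per-component streams, so runs are bitwise reproducible per seed. The
ground-truth ledger records every planted feature (motif coordinates,
per-peak AT/motif/TpA/noise draws, subset labels, promoter groups and
spacer AT%) and suffices to recompute each expected pipeline summary.

**What the generator does not emulate:** read-level data and coverage
tracks, codon structure and repeats, operon structure, replication-strand
skews, realistic intergenic length distributions, and higher-order
sequence correlations beyond the planted features. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure, not performance on real sequencing artefacts (mappability,
duplicate reads, peak-calling noise).

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive everywhere in the public surface
  (GFF3 convention); BED output converts to 0-based half-open on write.
- Merging with threshold 0 is the identity partition; equal summits are
  not linked (distance 0 is not < 0).
- All-N sequences are composition errors, never silently zero.
- Constant enrichment vectors make rank correlations undefined and raise.
- Fisher strata with no in-stratum genes are skipped, not reported as p=1.
- KDE densities are renormalised on the analysis grid (trapezoid) to
  tolerance 1e-3.
- Problem sizes in tests (2.2-Mb synthetic genome, 500 peaks, 20-seed
  recovery batches, 100×5-kb scanner-oracle sequences) were chosen as the
  smallest scales at which the planted effects are statistically
  identifiable with comfortable margins.

## Known limitations

- The published analysis consolidated peaks with an external peak caller
  upstream; this package starts from called peak tables, so differences in
  upstream calling propagate.
- Spacer-length ranges and element widths per sigma factor are
  configuration, not reproduced literature values.
- Whether the original analysis scanned one or both strands for the
  flexible pattern, and whether expected oligonucleotide counts were
  per-peak or pooled, is not stated; both choices are explicit here
  (both strands genome-wide; per-region normalisation) and configurable.
- Reproducing the published peak-consolidation counts (1551 unique, 1002
  shared, 549 specific with 531 below fold 5, 1350 target genes) requires
  the study's supplementary peak table as input; the corresponding check
  runs only when that table is supplied by the user.
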