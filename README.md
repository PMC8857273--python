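# silencer-scope

Analysis toolkit for characterising the genome-wide targetome of a
**xenogeneic silencer** — a nucleoid-associated protein (H-NS, Lsr2, MvaT,
Rok, or the zinc-finger MucR/Ros family addressed here) that preferentially
binds and represses horizontally acquired, AT-rich DNA. It is written for
bacterial regulatory genomicists who have ChIP-seq peak tables, a
multipartite genome with annotation, an ortholog-cluster table and
expression data, and want the full downstream analysis as a reproducible
pipeline rather than a collection of one-off scripts.

## What it computes

- **Peak consolidation** — single-linkage merging of peaks across
  conditions/replicates (summits closer than 200 bp share a peak id),
  shared vs condition-specific classification, and target-gene assignment
  by the regulation window [−500, +100] bp around the start codon.
- **Flexible-motif scanning** — exact, indel-tolerant scanning for the
  class-A flexible pattern `TTxxxGxxxTxxxxxxxxxxTT` (periodic repeats of
  Ts; ±1 indel in each of the first two gaps, ±2 in the third), with
  per-region counts and kernel-density summaries of motif and summit
  positions relative to gene starts.
- **Composition statistics** — AT%, zero-order-Markov oligonucleotide
  usage deviation `obs(W) / [(L−k+1)·Π f(W_i)]`, per-word binding
  preference (Spearman's ρ between word deviation and recruitment level
  across peaks), its regression on genome-wide deviation, and Pearson
  correlations of recruitment with AT% and motif count.
- **Promoter analysis** — −35/−10 position-specific scoring matrices per
  sigma factor (RpoD, RpoH1, RpoH2, RpoE2, RpoN), paired-element genome
  scans under spacer-length constraints, intergenic/intragenic
  classification, and Welch t-tests of spacer AT% between target- and
  non-target-associated promoters.
- **Pangenome integration** — hierarchical conservation subsets (I genus
  core, II species core, III near-strain shared, IV strain-specific) from
  an ortholog-cluster table, Fisher enrichment of targets by replicon and
  subset, gene AT% and expression by group, and the trend of subset
  composition across recruitment levels.
- **Synthetic data** — a deterministic generator of multi-replicon
  genomes with AT-rich islands, planted motifs, a recruitment model
  `fold = max(1+ε, β₀ + β_AT·AT% + β_motif·m + β_TA·(dev_TA−1) + N(0,σ))`,
  subset-structured expression and planted promoters, with a ground-truth
  ledger for every feature (see `docs/methods.md`).

## Worked example

```python
import silencerscope as ss
from silencerscope.composition import at_percent, binding_preference, recruitment_correlations
from silencerscope.peaks import central_region
from silencerscope.synthetic import SyntheticConfig, generate

ds = generate(SyntheticConfig(seed=1))          # 2.2-Mb genome, 500 peaks
merged = ss.merge_peaks([ds.peak_records], genome=ds.genome)
print("merged peaks:", ss.classify_condition_specific(merged))

targets = {a.gene_id for a in ss.assign_targets(merged, ds.genes)}
print("target genes:", len(targets), "of", len(ds.genes))

spec = ss.FlexPatternSpec()
triples = []
for p in merged:
    region = central_region(p, ds.genome)
    n = len(ss.scan_flexible(region.sequence, spec, "both"))
    triples.append((at_percent(region.sequence), n, p.max_enrichment))
cor = recruitment_correlations(triples)["raw"]
print(f"fold vs AT%:   r = {cor['pearson_at']:.3f} (p = {cor['p_at']:.2e})")
print(f"fold vs motif: r = {cor['pearson_motif']:.3f} (p = {cor['p_motif']:.2e})")

regions = [(p.peak_id, central_region(p, ds.genome).sequence, p.max_enrichment)
           for p in merged]
prefs = sorted(binding_preference(regions, k=2), key=lambda q: -q.rho)
print("top dinucleotide preferences:",
      ", ".join(f"{q.word} (rho={q.rho:.2f})" for q in prefs[:3]))
```

prints

```
merged peaks: {'total': 500, 'shared': 324, 'condition_specific': 176, 'condition_specific_low_fold': 165}
target genes: 513 of 1658
fold vs AT%:   r = 0.548 (p = 1.59e-40)
fold vs motif: r = 0.415 (p = 2.87e-22)
top dinucleotide preferences: TA (rho=0.23), GG (rho=0.13), GC (rho=0.12)
```

All 500 planted peaks are recovered as distinct merged peaks; roughly
two thirds are shared between the free-living and bacteroid conditions and
almost all condition-specific peaks are weak (fold < 5). About 30% of
genes are targets. Recruitment rises with both AT% and flexible-motif
count of the 200-bp central regions, and the TpA step — the most flexible
dinucleotide, the silencer's signature — ranks first among the 16
dinucleotide binding preferences.

A command-line interface mirrors the library
(`silencer-scope synth|ingest|peaks|flexmotif|promoters`); run any
subcommand with `--help`.

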