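# Methods

This note documents the models, parameter choices and numerical conventions
behind `bsakit`, and what the simulator-driven tests do and do not
demonstrate about real data.

## The simulated experiment

The generator forward-simulates a BSA-seq design: an F2 population from a
cross of two inbred parents (wild-type and mutant), phenotyped for a
quantitative trait and bulked at the phenotypic extremes.

**Genomes.** Markers are placed uniformly at random at `marker_density`
(default 100 per Mb). Each F2 gamete is a Markov walk along the marker map:
the parental origin at the first marker is a fair coin, and origin switches
between adjacent markers with the Haldane recombination fraction
`r = (1 − e^(−2d/100))/2`, where `d` is the genetic distance in cM (physical
distance × `recomb_rate_cm_per_mb`). No crossover interference, no mutation.
Genotype dosage at each locus is the sum of two independent gametes, so a
single locus segregates 1:2:1.

**Desk-scale genome compression.** The default genome is a single 20 Mb
chromosome standing in for a ~1 Gb genome. Genome-wide outlier thresholds
(ED median + 3 SD) are only meaningful when most of the genome is *unlinked*
to the QTL, which is a property of total genetic length, not physical
length. The default recombination rate is therefore 120 cM/Mb so the 20 Mb
toy genome carries ~2400 cM — the genetic length of the soybean consensus
map — preserving the linkage structure of a genome-scale scan under ~50×
physical compression. When simulating physically realistic chromosomes,
set `recomb_rate_cm_per_mb` to a per-bp realistic value (≈1–4).

**Trait and bulks.** Phenotype = `trait_baseline` + Σ additive effects ×
dosage + N(0, `env_sd`). Defaults emulate the study lines: baseline 17.98
nodes, one QTL of 3.05 nodes per allele (so opposite homozygotes differ by
6.1 nodes, the parental gap), environmental SD 1.0 node. Bulks are the top
and bottom `bulk_size` individuals by phenotype; ties break by individual id
(stable sort) for reproducibility. The default `bulk_size` is 32 with the
population default of 322; the source design reports the bulk size
inconsistently as 32 or 33, so it is exposed as a parameter rather than
guessed.

**Reads.** Per site and bulk, total depth ~ NegativeBinomial with mean
`mean_depth` (default 30, matching ~30× bulk coverage) and dispersion
`depth_dispersion` (default 10, giving variance ≈ mean + mean²/10, a
realistic overdispersion; `inf` recovers Poisson). Mutant-allele reads ~
Binomial(depth, f′), f′ = f(1−e) + (1−f)e with per-read error rate `e`
(default 0.002, post-filter Illumina scale). Parents are emitted error-free,
homozygous for opposite alleles at every marker (the definition of an
informative site), with Poisson depth 40. The mutant parent always carries
ALT, so the index counts ALT reads on simulated data; on real data the
polarization follows the mutant parent's genotype call per site.

**What the simulator does not emulate:** read-level errors correlated along
reads or FASTQ output, linkage disequilibrium beyond the marker map of a
single F2 meiosis (no ancestral LD), dominance, epistasis, segregation
distortion, mis-set parental genotypes, structural variants, and mapping
artifacts (the QC annotations QUAL/QD/MQ/FS are drawn from passing ranges;
filter behaviour on failing sites is exercised by handmade records in the
tests). Passing tests therefore demonstrate correctness of the inference
given the model's sampling assumptions, not robustness to alignment or
calling artifacts in real data.

## Filtering

Hard filters keep biallelic sites with QUAL ≥ 30, QD ≥ 2.0, MQ ≥ 40,
FS ≤ 60.0, boundaries inclusive exactly as written; sites missing an
annotation are dropped and counted (GATK hard-filter practice), never
imputed. Informative-site selection requires the parents to be called
homozygous for opposite alleles — the standard configuration that lets bulk
reads be polarized by parental origin; heterozygous-parent sites are
uninformative for an F2 and are dropped. "Adequate coverage" is read as
total (ref+alt) depth ≥ 4 in *both* bulks — the conservative reading, since
the source does not say which bulk. The two stages report separate audit
tables that reconcile exactly with input − output.

## Association statistics

Per-site: `index_b` = mutant-allele reads / total reads in bulk `b`;
`Δ = index_high − index_low` kept signed in output (peaks positive when
selection favours the mutant allele in the high bulk), thresholded on |Δ|.
`ED` is the Euclidean distance between the bulks' two-allele frequency
vectors; for biallelic sites `ED = √2·|Δ|` (a tested invariant). The
`ed_power` exponent (default 1 — the literal distance; 4–5 are common in
practice to sharpen peaks) is configurable.

Smoothing: overlapping sliding windows, default 1 Mb window / 100 kb step,
value = arithmetic mean of the per-site statistic (median available);
windows with fewer than `min_variants` sites (default 10, i.e. one tenth of
the expected ~100 sites per window at default density) are masked and never
enter thresholding or region calling. Window membership uses 0-based
half-open arithmetic: a 1-based site `pos` is in `[start, end)` iff
`start ≤ pos−1 < end`.

### Δ-index null and confidence thresholds

The null hypothesis is no locus–trait association. Its sampling model has
two stages, matching how the data are generated: (1) *bulk composition* —
each bulk is a draw of `bulk_size` F2 individuals, so its allele frequency
is `Binomial(2·bulk_size, 1/2) / (2·bulk_size)`; (2) *read sampling* —
`Binomial(observed depth, frequency)` per bulk. Each of `n_permutations`
(default 1000) iterations redraws both stages independently per site at the
observed depths. This is the standard simulation null for QTL-seq-style
confidence intervals; omitting stage (1) (`bulk_size=None`) leaves pure
read-sampling noise, which understates the null variance of finite bulks.

Two scopes are implemented:

- `scope="site"` (default): per-site null |Δ| quantiles at each confidence
  level (0.90/0.95/0.99) are averaged over the sites of each window, giving
  a per-window threshold track (wide, depth-aware envelopes — the per-site
  CI reading). A genome-global pooled per-site quantile is also reported.
- `scope="window"`: windowed null means pooled across iterations and
  thresholded at their global quantile. This variant measures only the
  *standard error* of a window mean; because bulk-composition deviations
  are shared by all linked sites in a window while the null redraws them
  independently per site, it is anti-conservative on real (linked) data and
  is provided for comparison, not as the default.

Thresholds are deterministic given a seed; a convergence test requires the
0.95 threshold's SD over 10 reseeds to stay below 5% of its mean at 1000
iterations.

### ED threshold

Genome-wide `median + k·SD` (default k = 3) over unmasked window values,
using the *sample* SD (n−1 denominator) — stated explicitly because the
convention changes the threshold. Requires ≥ 2 unmasked windows. Note this
is an outlier rule: it presumes most windows are null, which is why the
desk-scale genome must carry genome-scale genetic length (above).

## Region calling and combination

Maximal runs of consecutive unmasked windows with `stat_mean > threshold`
(strict) span one region from the first window's start to the last window's
end. No gap bridging by default (`max_gap_windows=0`); because windows
overlap when step < window, physically overlapping run-spans are merged so
each output set is disjoint and sorted. Coordinates snap to window
boundaries — no sub-window refinement, matching the method's resolution.

Combination is base-pair-level interval algebra on half-open intervals. The
default is the strict intersection of all four sets (Δ and ED × SNP and
InDel), equivalent to intersecting methods within each variant type and then
across types; union is available for sparse-InDel genomes. Variant types
with no sites are skipped with a warning rather than silently emptying the
intersection. Spans are reported in Mb (10⁶ bp) to 2 decimals, and
per-chromosome shares as span/total × 100 to 2 decimals.

## Annotation and effects

Gene–region overlap uses the any-overlap (≥ 1 bp) rule so boundary genes are
not silently lost; a `containment` flag restores the strict located-within
reading. Effect classification: SNPs in CDS are translated codon-wise
(reverse-complement on minus strand, phase-aware); stop gains/losses fold
into nonsynonymous (two-class prioritization). Coding InDels are frameshift
iff the net length change mod 3 ≠ 0, else in-frame. InDels whose changed
bases straddle a CDS boundary are conservatively classified noncoding with a
warning — a documented limitation. Only the first transcript per gene is
used when several exist. A REF allele that disagrees with the reference
sequence raises an error naming the site. The classifier is tested against a
brute-force oracle that translates the entire CDS before and after each of
1000 random variants, and against a genome-mirroring strand-symmetry check.

Enrichment is the upper-tail hypergeometric test (p = P[X ≥ k]) per term
over a user-supplied two-column gene→term map, BH-FDR corrected, significant
at FDR < 0.05. Candidates must be a subset of the background (error
otherwise); k = 0 gives p = 1 under the upper-tail convention.

## Integration

DEGs: FDR strictly < 0.01 and |log2FC| ≥ 1 — the boundary conventions follow
the printed rule exactly (strict on FDR, inclusive on fold change).
Transcript-level tables reuse the same operations through a
transcript→gene map; no isoform statistic is computed. Consistent genes are
DE in all declared contrasts, by default with the same direction everywhere.
Metabolite fold change is mutant/wild-type, so "down in the mutant" is
FC ≤ 0.5; compounds detected in exactly one line are "exclusive"
(directional toward the detecting line) and count as differential; compounds
detected in neither line are excluded with a log entry. The final report has
one row per candidate gene, ranked by (DE consistency, frameshift count,
nonsynonymous count, gene id) — deterministic bytes given identical inputs.

## Problem sizes used in tests and the acceptance script

Whole-pipeline checks simulate one 20 Mb chromosome (≈2400 cM) with 2000
markers, 300 F2 individuals, bulks of 32, ~30× depth, and one QTL of 3 trait
units against environmental SD 1 — 20 replicate seeds each for QTL recovery
(expect a combined Δ∩ED region containing the QTL) and for the null control
(expect zero Δ-index regions at the 0.95 level). These sizes keep a full
20-replicate sweep around a minute on one CPU while preserving the
signal-to-background structure of a genome-scale scan. Unit-level checks use
smaller genomes (0.5–5 Mb) and exhaustive or brute-force oracles.

## Known limitations

- The Δ-index null ignores linkage between sites *within* an observed
  window (each null site is independent); the per-site-envelope scope makes
  this conservative in practice, but windows of tightly linked sites share
  drift that the window-scope variant would misjudge.
- ED's median + 3 SD is a heuristic outlier rule with no stated error rate;
  on genomes where a large fraction of windows are linked to a QTL it loses
  power (see genome-compression note).
- Effect classification handles neither splice-region scoring nor
  regulatory annotation, and multi-gene overlaps are resolved to the first
  gene by coordinate.
- Enrichment treats terms independently (no GO DAG propagation, no pathway
  topology).
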