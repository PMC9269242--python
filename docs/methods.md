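# Methods

This note documents the statistical model behind `bsascan`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing a run.

## 1. Pool indices and filters

For a biallelic site with REF/ALT read depths `(r, a)` in a pool, the
pool index is `a / (r + a)`, an estimate of the pool's ALT allele
frequency, and Δ(index) is the high-pool index minus the low-pool index.
A zero-depth pool leaves the index undefined; the depth filter must run
first, and `compute_index` raises on zero totals rather than guessing.

Pre-association filters run in a fixed, reported order (first matching
rule claims the removal, so the per-rule counts always reconcile with the
input count):

1. **multi-allelic** sites (flagged at VCF parse time, never silently
   dropped earlier, so they can be counted here);
2. **depth** — total depth below `min_depth` (default 4) in *either* pool;
3. **low index** — index below `min_index` (default 0.3) in **both**
   pools. The both-pool reading preserves high-|Δ| sites where one pool is
   legitimately near 0, and discards sites that look like shared
   sequencing error or a rare allele; `low_index_mode="either"` gives the
   stricter per-pool reading;
4. **equal genotype** — both indices in the same homozygous band
   (< 0.1 or > 0.9 on both sides; band width configurable). This is the
   operational form of "same genotype in both pools": at pool sizes of
   49 the read fraction of a truly fixed site stays inside a narrow band;
5. **parental recessive** (off by default) — only meaningful for
   cross-derived bulks; given a parental ALT-frequency map, sites where
   the low bulk's major allele contradicts the recessive parent are
   dropped. A natural population has no parents, hence the default.

## 2. Sliding-window scan and the simulated null

Windows are anchored at base 1 and stepped by `step_size` (defaults
2 Mb / 10 kb); a window exists whenever its start lies on the chromosome,
and tail windows are truncated but flagged. Window statistics are plain
arithmetic means of member-variant `index_high`, `index_low` and Δ.
Windows with fewer than `min_variants_per_window` members (default 10 —
enough to suppress single-variant spikes) are flagged unreliable and
excluded from region calling.

**Null confidence intervals.** Because depth varies site to site, the
null spread of a window mean is data-dependent, so CIs come from a
Monte-Carlo resampling null of "no allele-frequency divergence between
pools". The null is *two-stage*. At each member site, with
`p̂ = (alt_high + alt_low) / (depth_high + depth_low)`:

1. *bulk composition*: each pool's true ALT frequency is redrawn as
   `Binomial(2·pool_size, p̂) / (2·pool_size)` — a finite bulk of *m*
   accessions fluctuates around the population frequency with variance
   `p(1−p)/2m` even without any linkage to the trait;
2. *read sampling*: ALT read counts are redrawn as
   `Binomial(observed depth, bulk frequency)` at the observed per-pool
   depths.

Per replicate, the window mean Δ is recomputed and the CI is the pair of
empirical two-sided quantiles (`ci_levels`, default 0.95 and 0.99;
`null_reps` default 10 000). Omitting stage 1 (`pool_size=None`) gives a
reads-only null; at the default design (pools of 49, ~40× depth) the
bulk-composition variance is roughly 40 % of the read-sampling variance,
and the reads-only null is visibly anti-conservative (≈9 % of causal-free
windows fall outside a nominal 95 % interval versus ≈5 % for the
two-stage null). CIs are per-window by default; `ci_scope="genome-wide"`
instead uses quantiles of the per-replicate maximum |window mean Δ| over
all windows, applied uniformly — a family-wise band for analysts who want
one.

**Calibration is measured under depth-only filtering.** The index-based
filters (rules 3–4 above) condition retained sites on the very statistic
the null resamples — e.g. removing sites with both indices < 0.3 trims
concordant draws and inflates the observed |Δ| of what remains (measured:
≈7 % outside a 95 % CI under default filters, ≈5 % with only the depth
filter). The coverage check in `experiments.null_ci_calibration`
therefore filters on depth alone and uses non-overlapping windows, so the
outside fraction averages over effectively independent windows.

**Region calling.** A window is significant when |mean Δ| reaches
`delta_threshold` (default 0.90, applied to the window mean Δ) **and**
its mean Δ lies outside the CI at the first configured level; the mode is
switchable to threshold-only or CI-only. By default a window counts only
if significant in *both* the SNP and the InDel track (computed on an
identical grid — a grid mismatch is an error); overlapping significant
windows merge into candidate regions, which carry the peak Δ, the
supporting tracks, and the genes they overlap. As an optimization,
`scan_track(..., ci_windows="above-threshold")` computes CIs only for
threshold-passing windows; in the default AND mode this cannot change the
called regions, because sub-threshold windows are insignificant either
way.

## 3. Consequence classification

Variants are classified against gene models (per-mRNA) into a mutually
exclusive taxonomy, with precedence when a variant touches several
regions of one or more genes:

```
exonic > splicing > intronic > upstream/downstream (joint)
       > upstream > downstream > intergenic
```

Definitions: upstream/downstream are the 1-kb flanks of the transcription
start/end (strand-aware); the joint class is upstream of one gene while
downstream of a *different* gene; splicing is the 2 intronic bases
adjacent to each CDS/intron junction (multi-exon transcripts only) and
outranks intronic; everything inside the transcription bounds but outside
the CDS is intronic (the gene model carries no UTR information).
Alleles are normalized by trimming shared prefix/suffix bases, so both
VCF-anchored (`ATG > A`) and dash-style (`TG > −`) indel encodings work.

Exonic SNVs rebuild the affected codon from the genome with the variant
substituted (coding strand, standard nuclear code, `phase` honored) —
synonymous, non-synonymous, stop-gain or stop-loss. Exonic indels are
frameshift iff the net inserted/deleted length is not a multiple of 3;
for indels fully inside the CDS the first affected codon of the mutated
coding sequence is additionally checked for an immediately created or
eliminated stop. Indels spanning a CDS boundary stay exonic and fall
back to the length rule. When several transcripts overlap a variant the
worst effect is reported, with all gene ids attached. REF alleles are
validated against the genome; a mismatch or out-of-range position raises
with coordinates.

The test suite holds this classifier to an independent brute-force oracle
(literal region definitions, whole-protein translation) at every position
× every substitution of a toy contig, and to strand-flip invariance.

## 4. Gene prioritization, haplotypes, enrichment

Genes in a candidate region are ranked by the worst effect they carry:
`frameshift/stop > non-synonymous > other-genic (synonymous, splicing,
intronic) > regulatory (up/downstream) > none`, ties broken by position;
the top gene of a region is its headline candidate.

The haplotype comparison contrasts phenotypes of REF vs ALT carriers per
environment. The test is Welch's unequal-variance two-sample *t*-test — a
robust default for unequal group sizes; a label-permutation p-value
(`permutation_pvalue`, add-one corrected) is provided as a cross-check
and agrees within Monte-Carlo error on small groups. Heterozygous calls
are excluded by default (`include_het=True` scores them half-REF in the
allele fractions); environments with fewer than 2 accessions in either
group are reported untested rather than silently skipped.

GO over-representation is the one-sided hypergeometric (Fisher upper
tail): `p = P(X ≥ k | N, K, n)` with expected count `K·n/N`. No
multiple-testing correction is applied by default — results are flagged
at raw `p < α` — with Benjamini–Hochberg q-values behind a flag. When
only a printed report row is available, `backsolve_background` recovers
`N = round(K·n / expected)` so the p-value can be recomputed from the
published Annotated/Count/Expected columns; per-ontology background
sizes are supported because annotation services typically use them.

## 5. The synthetic generator

`synthetic_data` emulates an extreme-pool resequencing experiment on a
natural population. Defaults define the reference scenario and are not
tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| accessions / pool size | 1525 / 49 | the emulated design |
| chromosomes × length | 20 × 10 Mb | desk-scale genome at realistic window counts |
| variants | 20 000 (1 / 10 kb) | ~200 SNPs per 2-Mb window after filtering |
| indel fraction | 0.15 | matches the SNP:InDel ratio of typical resequencing |
| multi-allelic fraction | 0.01 | exercises the filter-report path |
| causal site | effect 40 µg·g⁻¹ at ALT frequency 0.4 | per-environment h² ≈ 0.38 |
| phenotype | μ = 230, σₑ = 35 µg·g⁻¹, 5 location-years (offsets N(0, 10)) | total-tocopherol scale |
| depth / error | Poisson(40) per pool per site, ε = 0.001 | ~40× average depth |
| neutral allele-frequency law | Uniform(0.05, 0.5) | folded spectrum of a diverse panel |
| LD mode | on, Gaussian kernel exp(−(d/2.5 Mb)²) within 6 Mb | see below |

Genotypes are site-wise Hardy–Weinberg draws (dosage =
`Binomial(2, p)` via one uniform against the cumulative thresholds);
phenotype per environment = μ + environment offset + Σ effect·dosage +
N(0, σₑ). Pools are the top/bottom *n* accessions by phenotype (mean
across environments by default), ties broken by accession id. Selecting
on the 5-environment mean divides the residual noise by √5, which is what
lets pools of 49 out of 1525 nearly fix for opposite alleles at a locus
of only h² ≈ 0.38 — the multi-environment replication is doing real
statistical work, as in the emulated design. Pooled reads per site per
pool: true pool frequency q = mean dosage / 2, depth ~ Poisson(λ), ALT
reads ~ Binomial(depth, q(1−ε) + (1−q)ε), equal DNA contribution per
accession assumed.

**Block LD.** Independent sites would put the entire causal signal on one
marker and no 2-Mb window mean could approach the 0.90 threshold. The LD
mode therefore copies the causal dosage into each flanking site with
probability `exp(−(d/ld_scale)²)` (scale 2.5 Mb, cutoff 6 Mb), so a
flanking site's expected Δ is that probability times the causal Δ and the
windowed scan sees a peak of realistic width (window mean Δ ≈ 0.93–0.95
at the default design). This is a deliberately stylized haplotype model —
much longer-ranged than real soybean LD, scaled to the 10-Mb toy
chromosomes, and with no recombination map or population structure.

`emit_toy_genome` writes a FASTA/GFF3/GO-table trio for the causal
chromosome: a 10-kb designated region centred on the causal site hosting
exactly six two-exon genes (one receives the causal variant at a CDS
position chosen, by codon check at emission, to be non-synonymous), 24
background genes elsewhere, and a GO table that makes five of the six
region genes share one designated term against a 2 000-gene synthetic
background. Gene ids (`TOY.*`), term ids (`GO:9000001`…) and the
background are all synthetic.

**What passing tests show — and don't.** The generator reproduces the
statistical skeleton the scan relies on (HWE genotypes, truncation
selection into finite bulks, depth-varying binomial reads, linked
flanking signal). It does not emulate population structure, kinship,
real LD decay, reference bias, mapping artifacts, indel-calling error
modes, or multi-locus genetic architectures. Recovery of the causal
window in ≥18/20 seeds here demonstrates the pipeline's correctness
under its own assumptions, not field performance on real germplasm.

## 6. Problem sizes and determinism

The acceptance runs use the default scenario with `null_reps=1000` for
region calling (the CI enters only through a clear-cut AND with the 0.90
threshold, where 1 000 replicates resolve the decision) and
`null_reps=10 000` for the coverage check, on 12 default-sized
chromosomes (~600 non-overlapping 200-kb windows) — sizes chosen so the
whole study re-runs comfortably on one CPU. Every stochastic stage takes
a `numpy` `Generator` or derives one from a single seed via
`SeedSequence.spawn`; identical seeds give byte-identical outputs
(fixed filter order, mergesort for site ordering, id-based tie-breaks).

## 7. Known limitations

* Per-mRNA classification with worst-effect summarization; no canonical
  transcript selection and no UTR-aware categories.
* The equal-genotype filter band (0.1) and the both-pool reading of the
  low-index rule are conventions, configurable but not estimated.
* The hypergeometric test ignores the GO DAG (no term propagation).
* The two-stage null assumes equal DNA contribution per accession and
  HWE within bulks; strong inbreeding or unequal pooling would need a
  different stage-1 law.
* QC-rate helpers (`effective_rate`, `mapping_rate`) are report
  arithmetic over externally supplied counts; the pipeline itself starts
  from a VCF and never touches reads or alignments.
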