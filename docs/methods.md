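# Methods

`subspec` detects and profiles *population subspecies*: within-species
clusters of metagenomic populations with distinct single-nucleotide-variant
(SNV) allele patterns, a taxonomic resolution between species and strain.
This note documents the statistical procedure, its assumptions, the
parameters that matter, and what the synthetic-data generator does and does
not emulate.

## Input model

The unit of analysis is one species observed across many metagenomes.  The
raw evidence is per-position base counts, either parsed from `samtools
mpileup` default text (one coverage/bases/qualities triple per sample) or
read from the package's SNV-table TSV dialect.  Coordinates are 1-based,
matching mpileup and VCF.  Strand is ignored ('.'/',' and upper/lower case
merged): metagenomic allele counting is strand-agnostic.  Base qualities
are parsed but not used for filtering; no quality threshold is applied.

**SNV calling.** A (position, alt allele) pair becomes an SNV row when, in
at least one sample, the alt base count is at least `min_allele_count` (4)
and its frequency at least `min_allele_freq` (0.01) at a site with coverage
at least `min_coverage_per_site` (5 reads).  Multi-allelic positions yield
one row per alt allele; a row's frequency uses the denominator ref + that
alt, keeping it in [0, 1].

**Filtering.** Samples whose mean coverage over SNV positions is below
`min_mean_coverage_per_sample` (5) are dropped; SNVs observed (coverage >=
`min_coverage_per_site`) in fewer than `min_sample_prevalence` (0.5) of the
retained samples are dropped.  The two steps interact, so they are iterated
to a fixed point — this makes the filter idempotent and deterministic,
and independent per species, so species can be processed concurrently with
bit-identical results.  All thresholds are config/CLI flags.

**SNV profiles.** The frequency matrix holds f = alt / (ref + alt) per SNV
and sample, missing where site coverage is insufficient (and at covered
sites whose reads are all third alleles).  Missing values are never
imputed.

## Dissimilarities

For each sample pair, the default dissimilarity is the mean absolute
allele-frequency difference over jointly observed SNVs (a normalized
Manhattan distance; `euclidean_mean`, the root mean squared difference, is
an option).  Both lie in [0, 1].  Pairs sharing fewer than `min_shared`
(100) SNVs are *invalid* rather than imputed; samples invalid against every
other sample are excluded from clustering and reported.  With complete data
`mean_abs` is a metric (triangle inequality holds); with pairwise deletion
it is a dissimilarity, which is why clustering uses medoids.

## Discovery subset (quasi-phaseability)

Subspecies discovery requires samples whose within-sample population is
effectively a single haplotype cluster, so that its dominant alleles can be
read off directly.  A sample's *phaseability* is the fraction of
dataset-wide SNVs, among those it covers, whose major allele fraction
max(f, 1 − f) exceeds `major_freq_threshold` (0.9, strict: "in over 90% of
reads").  The sample enters the discovery subset when phaseability is at
least `phaseable_snv_fraction` (0.8, inclusive: "at least 80%") and it
covers at least `min_snv_coverage_fraction` (0.8) of the dataset-wide SNVs.
The coverage-fraction condition, together with the mean-coverage filter,
also stands in for "the species is abundant in the sample", for which no
separate abundance cutoff is applied.  If no sample qualifies, subspecies
cannot be detected for the species and the pipeline records that outcome.

## Cluster number by prediction strength

Discovery samples are clustered with k-medoids (PAM) on the dissimilarity
matrix.  PAM here is fully deterministic: initialization takes the most
central sample and then greedily the sample farthest from the chosen seeds;
the swap phase exchanges (medoid, non-medoid) pairs while the total
within-cluster dissimilarity strictly decreases (tolerance 1e-12), all ties
breaking to the lowest index.  Randomness enters only through subsampling.

The number of clusters is chosen with the prediction strength of
Tibshirani & Walther.  Each of `n_iterations` (100) iterations splits the
samples into train/test halves (`train_fraction` 0.5), clusters both into k
medoid clusters, classifies each test sample to its nearest train medoid,
and scores each test cluster by the fraction of its member pairs that the
train classifier co-assigns; the iteration's score is the minimum over test
clusters.  ps(k=1) is 1 by definition.  Test clusters with fewer than two
members are degenerate: they contribute 1 to the minimum (the co-membership
criterion is vacuous for a singleton) and the iteration is flagged.

**Selection rule.** k_selected is the largest k in 1..`k_max` (10) that the
estimate *accepts*: at most half of its iterations degenerate, and the mean
ps over non-degenerate iterations at least `ps_threshold` (0.8) *after
subtracting one standard error of that mean*.  Two deliberate choices are
embedded here.  First, degenerate iterations are excluded from the
selection estimate: above the true cluster number PAM tends to isolate
tiny spurious clusters, and the singleton convention would otherwise
inflate mean ps exactly where it must not.  Second, the one-standard-error
margin keeps borderline spurious splits (whose informative mean hovers just
above threshold by sampling noise) from being accepted; in simulations this
margin moved recovery of the planted cluster number from roughly 90% to
over 99% of runs without ever rejecting a well-supported k.  Both full and
informative means are reported in `ps_per_k.tsv`.

Per-sample assignment confidence (*stability*) is the fraction of the
selected k's subsampling iterations in which the sample is classified (by
that iteration's train medoids) together with the majority of its final
cluster.  Clustering the full discovery subset at k_selected gives the
final assignments.  The subset must hold at least `min_discovery_size` (20)
samples; below that the species is reported as having insufficient
discovery samples.

## Genotyping alleles and profiling

For each cluster, distinctive marker alleles are SNVs whose median
frequency within the cluster is at least `within_threshold` (0.8) while the
maximum median across all other clusters is at most `outside_threshold`
(0.2) — the `alt_high` state — or the symmetric rule on 1 − f (`alt_low`).
Markers are ranked by the (within − outside) margin, ties broken by SNV id,
and capped at `max_markers` (100) per cluster.  A cluster with no markers
is flagged unprofilable but retained in the report.

Subspecies abundance in *any* metagenome (discovery member or not) is the
median over the cluster's observed markers of the marker-oriented frequency
(f for `alt_high`, 1 − f for `alt_low`); the mean is available as an
option, the median being robust to individual marker failures.  An estimate
is reported only when at least `min_markers_observed` (5) markers are
covered.  A normalized view rescales a sample's estimates to sum to 1 when
every cluster has an estimate; both views are written.

## Gene association and pN/pS

Subspecies-specific genes are found by Spearman rank correlation between
each gene's abundance and each cluster's abundance across shared samples
(at least `min_assoc_samples`, 10), with Benjamini–Hochberg FDR across all
gene × cluster tests of the species.  Spearman is used because metagenomic
abundances are compositional and heavy-tailed, and rank correlation is
invariant to monotone scaling.  Constant gene vectors are skipped with a
logged reason.

Purifying selection is estimated per gene as pN/pS over observed SNVs (a
row's presence in any sample counts once; counts are not
frequency-weighted).  Expected site counts follow the Nei–Gojobori
equal-rates convention: each codon position contributes n/3 nonsynonymous
sites where n of its three possible substitutions change the amino acid
(stops distinct), so nonsynonymous + synonymous sites equal the CDS length
exactly.  pN/pS = ((n_obs + pc)/n_sites) / ((s_obs + pc)/s_sites) with
pseudocount pc = 0.5 guarding empty categories.  The standard genetic code
is used (NCBI tables 1 and 11 translate identically; start codons are
ordinary codons here).  CDS coordinates come from GFF3 (1-based inclusive,
strand applied); genes with length not a multiple of 3 or nonzero phase are
skipped with a warning, as are SNVs at ambiguous reference bases.

## Synthetic data

The generator abstracts a genome-mixture benchmark to consensus haplotypes:
each of `k_true` subspecies is a 0/1 alt-allele pattern over `n_snvs`
positions.  `divergence` (default 0.8) is the fraction of positions whose
pattern is non-constant across clusters; at each such position a uniformly
random subset of clusters (size uniform on 1..k−1) carries the alternate
allele.  For k = 2 any two clusters therefore differ at exactly the
divergence fraction; for k ≥ 3 at roughly half to two-thirds of it —
simultaneous pairwise separation above 2/3 is combinatorially impossible
for three or more binary haplotypes, a bound the generator's rejection
check respects.  Including single-carrier patterns guarantees every cluster
owns distinctive alleles, as real clades do.

Samples draw true frequencies as mixture-weighted consensus plus truncated
Gaussian jitter (`within_noise` 0.05, clipped to [0, 1]); coverage is
Poisson(`coverage_mean` 50) per site and alt counts Binomial(coverage, f).
Defaults (60 samples, 200 SNVs) are the desk-scale study conditions used
throughout testing.  Gene abundances are lognormal, with an
`assoc_gene_fraction` of genes tied to a cluster's true abundance by a
per-gene scale plus additive lognormal noise.  A separate neutral-gene
simulator emits random stop-free CDS contigs with SNVs placed uniformly at
random, under which pN/pS is ~1 by construction of the site normalization
(a few percent above 1 in practice, from the ratio's convexity at small
synonymous counts).

What the generator does **not** emulate: linkage and recombination,
coalescent genealogies, sequencing error, mapping artifacts, compositional
coupling between species, or uneven genome coverage.  Passing tests
therefore demonstrate the statistical machinery — clustering, marker
extraction, profiling, calibration — under the stated noise model, not
robustness to every artifact of real metagenomes.

## Pipeline, determinism, reporting

A YAML config drives the per-species chain; every threshold above is a
config key, so stricter or more lenient subpopulation definitions are
one-line changes.  Per-species seeds derive from the global seed and a hash
of the species id, so results are independent of species order and of which
other species run; serial and thread-pool execution produce byte-identical
TSVs.  Validation fails fast before any computation; one species failing is
isolated from the rest.  The plain-text summary and HTML report render the
TSV artifacts (re-read, not recomputed), with the prediction-strength curve
embedded as an inline image.

## Validation problem sizes

The test suite validates recovery at the generator's default study
conditions (60 samples, 200 SNVs, 50× coverage, divergence 0.8, jitter
0.05) over 100 simulation seeds per true cluster count in {2, 3, 4};
oracle-equivalence checks use 100 random instances each.
`scripts/acceptance.py` recomputes the same quantities with 30 seeds per
cluster count — enough for a stable rate estimate while keeping a single
run to a few minutes — alongside the full-size oracle, mixture, pN/pS and
FDR checks.

## Known limitations

- Subspecies are assumed discrete and near-clonal within discovery
  samples; continuous gradients or heavy within-sample mixtures lower
  phaseability and suppress detection (by design).
- The selection rule is conservative: true clusters that are tiny relative
  to the discovery subset (degenerate in most test splits) or weakly
  separated may be merged.
- pN/pS uses SNV presence, not frequencies, and assumes phase-0 CDSs.
- Dissimilarities from few shared SNVs are suppressed rather than
  shrunk; samples with sparse profiles drop out instead of being imputed.
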