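# subspec

Detection and profiling of **population subspecies** in prokaryotic
metagenomes from single-nucleotide-variant (SNV) profiles.

Microbiome analyses are well served at the species level, and many tools
recover individual strains — but strains are rarely shared across hosts,
while species often hide ecologically distinct sub-lineages.  *Subspecies*
are the useful intermediate: within-species clusters of metagenomic
populations with distinct SNV allele patterns, stable enough to track
across cohorts and habitats.  `subspec` delineates them directly from the
data and then quantifies them in any metagenome, for researchers who
already have per-species read mappings (or SNV tables) across many
samples.

## Method

For each species, starting from per-sample allele counts:

1. **SNV profiles.** Call SNVs from `samtools mpileup` text (or load an
   SNV-table TSV), filter by coverage and prevalence, and form the matrix
   of alt-allele frequencies f = alt/(ref+alt) per SNV × sample.
2. **Dissimilarities.** d(a,b) = mean |f_a − f_b| over jointly observed
   SNVs (pairwise deletion; pairs with too few shared SNVs are invalid).
3. **Discovery subset.** Keep quasi-phaseable samples: at least 80% of the
   covered dataset-wide SNVs have one allele in over 90% of reads, so the
   sample's population is effectively a single subspecies.
4. **Clustering.** k-medoid (PAM) clustering of the discovery subset; the
   number of clusters is chosen by the prediction strength of Tibshirani &
   Walther, ps(k) = min over test clusters of the fraction of co-clustered
   test pairs that a train-half classifier also co-assigns, estimated over
   repeated 50/50 subsampling.  Confidence is reported per k (mean ± sd of
   ps) and per sample (co-clustering stability).
5. **Genotyping alleles.** SNV alleles near-fixed within one cluster
   (median frequency ≥ 0.8) and rare in all others (≤ 0.2) become
   subspecies markers.
6. **Profiling.** In *any* metagenome, each subspecies' relative abundance
   is the median marker-oriented frequency over its observed markers.
7. **Genes and selection.** Subspecies-specific genes by Spearman
   correlation of gene vs subspecies abundance with Benjamini–Hochberg
   FDR; per-gene purifying selection as
   pN/pS = ((N_obs+½)/N_sites) / ((S_obs+½)/S_sites) with Nei–Gojobori
   site counting.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 3-subspecies dataset with known truth, then run the discovery
chain:

```sh
subspec simulate --seed 7 --out demo/sim
# simulated 3 subspecies, 60 samples, 200 SNVs -> demo/sim
subspec filter --snv-table demo/sim/snv_table.tsv --out demo/flt
# 200 SNVs x 60 samples retained
subspec dist --freq demo/flt/freq.tsv --min-shared 50 --out demo/dist
subspec discover --dist demo/dist/dist.tsv --freq demo/flt/freq.tsv \
    --seed 7 --out demo/disc
# k_selected = 3
```

`demo/disc/ps_per_k.tsv` holds the model-selection evidence — prediction
strength is 1.0 at the true k = 3 and collapses for a forced 2-way split
of the three haplotype clusters:

```
k   mean_ps   mean_ps_informative   sd_ps    n_degenerate
1   1.0       1.0                   0.0      0
2   0.694     0.694                 0.251    0
3   1.0       1.0                   0.0      0
```

`clusters.tsv` lists each discovery sample's subspecies and stability
(fraction of subsampling iterations agreeing with its final cluster):

```
sample  cluster  stability
S001    2        1.0
S002    2        1.0
S003    1        1.0
```

and `genotyping_alleles.tsv` the distinctive marker alleles, here
perfectly fixed within their cluster and absent outside:

```
cluster  snv_id             state     within_freq  outside_freq
1        contig_1:113:C>A   alt_high  1.0          0.0
1        contig_1:115:G>C   alt_low   1.0          0.0
```

`subspec profile --freq ... --markers demo/disc/genotyping_alleles.tsv`
then estimates subspecies abundances in any other sample set, and
`subspec run --config run.yaml` drives the whole per-species pipeline
(including gene association, pN/pS and the plain-text/HTML report) from
one YAML file.

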