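# schpipe

Detection and characterization of **spatial co-mutation hotspots (SCHs)** —
groups of genes that are both recurrently co-mutated across tumor samples
and spatially proximate in Hi-C chromatin conformation.

Somatic point mutations in cancer often co-occur in the same patient
("co-mutations"), and part of that non-randomness tracks the 3D folding of
chromatin: genes whose loci touch in the nucleus are co-mutated more often
than their linear distance alone predicts.  `schpipe` is for computational
cancer-genomics researchers who want a tested, reusable implementation of
that analysis: it takes a somatic mutation cohort (MAF-like TSV),
per-chromosome 40 kb Hi-C contact matrices, a gene annotation, a reference
FASTA, pathway gene sets (GMT), a driver-gene list and a CTCF signal track
(bedGraph), and produces SCH calls plus the full battery of
characterization statistics.  A seeded synthetic-data module generates all
of these inputs with planted ground truth, so every stage is testable
without any external downloads.

## The method

**Co-mutation ("DB") clustering.**  The cohort is collapsed into a binary
gene-by-sample matrix A with a_ij = 1 iff gene *i* is mutated at least once
in sample *j*.  Genes, ranked by mutated-sample count, are greedily
clustered by normalised Hamming similarity
s_ij = 1 − h_ij / n_sp (h_ij = Hamming distance of the two sample
profiles, n_sp = number of samples).  The similarity threshold is chosen
from {0.1, …, 1.0} as the one whose clustering most significantly separates
intra- from inter-cluster Hi-C contact frequencies (unpaired two-sided
t-test, smallest p wins).

**Spatial ("Hi-C") clustering.**  Each intra-chromosomal contact matrix A
is distance-normalized, a′_ij = a_ij / b_overall(|i−j|), where
b_overall(d) is the mean of the d-th off-diagonal; the Pearson correlation
c_ij between columns *i* and *j* of A′ gives the matrix C, and genes are
clustered by average-linkage hierarchical clustering on 1 − c between
their TSS bins (bin = ⌊(TSS−1)/40000⌋).

**SCHs.**  An SCH is any intersection (≥ 2 genes) of one DB cluster with
one Hi-C cluster.  Detected SCHs are then characterized by

* *proximity*: paired t-tests of co-mutated pair contacts against the
  overall and the gene-level distance backgrounds b_overall(d), b_gene(d);
* *mutational signatures*: each gene's mutations are typed into the 12
  ordered substitutions ref>alt over {A,C,G,T}; Jaccard distances between
  binary type profiles compare intra-SCH vs intra-DB/intra-HiC/inter-SCH
  dissimilarity, and a complementing score
  1 − 2·Σ_pairs min(n_x>y, n_y>x) / N (0 = perfectly complementary
  counts) is Z-tested against the pooled SCH background;
* *flank conservation*: 21-nt reference windows centered on each mutation
  (position 11) are scored by mean per-column Shannon entropy (bits,
  lower = more conserved) and Z-tested against size-matched random window
  groups;
* *pathways and drivers*: hypergeometric upper-tail enrichment per cluster
  (cluster p = minimum over pathways), enrichment fractions across p-value
  cutoffs, distinct-pathway coverage, and driver-gene percentages with
  two-proportion z-tests;
* *CTCF*: per-TSS mean signal in a ±5 kb window, SCH genes vs all genes.

## Worked example

Simulate a small planted cohort and run the full pipeline:

```yaml
# cfg.yaml
simulate:
  seed: 11
  n_chromosomes: 2
  bins_per_chromosome: 80
  bin_size: 5000
  n_genes: 80
  n_samples: 30
  n_planted_hotspots: 3
  hotspot_size_min: 4
  hotspot_size_max: 5
  hotspot_block_bins: 8
  background_mut_prob: 0.05
conservation_resamples: 100
```

```bash
schpipe run --config cfg.yaml --out-dir out
schpipe report --out-dir out
```

prints (abridged):

```
schpipe 0.1.0 run (seed 11)
DB clustering: threshold 1.0 -> 44 clusters (9 with >=2 genes)
proximity: co-mutated pair contact 16.1 vs overall 9.13 (p=1.54e-06) / gene-level 9.94 (p=4.8e-06)
SCHs detected: 3
planted-recovery pair F1: 1.000
complementing: {"background_score": 0.289, "mean_sch_score": 0.874, "z": 55.96, ...}
conservation: {"background_mean": 1.787, "mean_sch_score": 1.033, "z": -39.98, ...}
ctcf: {"mean_background": 1.433, "mean_sch": 2.732, "p": 2.4e-09, ...}
```

Reading this: the three planted hotspots are recovered exactly (pair-level
F1 = 1.0 against the generator's truth).  Co-mutated gene pairs sit in
contact 16.1 on average where distance-matched background pairs sit at
9.1–9.9 (paired t-test p ≈ 10⁻⁶).  Within SCHs the mutation types are
*less* complementary than the pooled background (complementing score 0.87
vs 0.29, Z ≈ +56 — hotspot mutations share a direction), and their 21-nt
flanks are far more conserved than size-matched random window groups
(1.03 bits vs 1.79 bits, Z ≈ −40).  CTCF-like signal at SCH-gene TSSs is
roughly double the all-gene background (p ≈ 10⁻⁹).  `out/report.json`
holds every number; `out/inputs/` holds the simulated MAF, BED, FASTA,
dense/COO Hi-C, GMT, driver list and bedGraph; cluster tables and the SCH
table are persisted alongside.

Each stage is also available separately (`schpipe simulate`, `cluster-db`,
`hic-background`, `cluster-hic`, `detect-sch`, `characterize-signatures`,
`characterize-flanks`, `enrich`, `ctcf-profile`) and as a library
(`import schpipe`).

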