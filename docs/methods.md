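# Methods notes

This note records the models behind `schpipe`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
design choices made where the method was genuinely open.

## Pipeline model and assumptions

The pipeline treats two independent sources of gene grouping as noisy
views of the same latent structure:

1. **Co-mutation clustering** assumes that genes hit by a shared mutational
   process co-occur across samples.  The binary gene×sample matrix
   deliberately discards multiplicity (a gene mutated twice in a sample
   counts once), and the greedy seeded pass assigns each gene exactly once:
   the top-ranked unclustered gene seeds a cluster and absorbs all
   remaining unclustered genes with Hamming similarity ≥ threshold in a
   single ordered scan.  Rank ties are broken lexicographically by gene id
   so runs are reproducible.
2. **Spatial clustering** assumes contact frequency decays with linear
   distance and that residual correlation structure after removing that
   decay marks loci that fold together.  Division by the off-diagonal mean
   (`A' = A / b_overall(d)`) makes every defined off-diagonal of `A'`
   average exactly 1; Pearson correlation of `A'` columns then captures
   shared long-range contact patterns.  Missing bins (fully absent
   columns) are masked and excluded from every statistic rather than
   imputed; because missingness is always whole-column, pairwise-complete
   correlation reduces to complete-row correlation on the unmasked
   submatrix.

An SCH is defined combinatorially (DB ∩ Hi-C intersection, ≥ 2 genes), so
its error rate inherits from both clusterings: a spurious SCH needs a
false co-mutation link *and* a false spatial link over the same gene pair.
This intersection acts as the pipeline's multiple-testing guard and is why
individual clustering stages may run at permissive thresholds.

### Threshold selection

The Hamming threshold is selected from {0.1, …, 1.0} by the smallest
two-sided unpaired t-test p-value between intra- and inter-cluster contact
frequencies — the significance alone decides, not the direction, and exact
p ties go to the larger (tighter) threshold.  Genes on chromosomes without
contact data are excluded from selection but retained in the clusters.
Consequence (measured, not hidden): the p-value that the intra/inter
comparison reports at the selected threshold is the minimum of ten
correlated tests and is anti-conservative — under the fully null generator
the comparison "passes" (p < 0.005 with intra mean > inter mean) in ≈ 3.5%
of replicates instead of the ≈ 0.25% a single test would give.  The same
comparison run at a fixed mid-grid threshold is calibrated (0/200 null
passes).  Both rates are reported by `scripts/acceptance.py`.

### Hierarchical-clustering cutoff

Average linkage runs on distance 1 − c.  The default tree cut is
**noise-aware**: merge only correlations exceeding `z0/√(n−3)`
(Fisher-approximate null standard error of a Pearson coefficient over `n`
complete observations), `z0 = 3`.  Rationale: a fixed constant ignores the
matrix size, while cutting at the mean pairwise distance (the obvious
data-adaptive rule) merges roughly half of the noise mass and collapses a
250-bin chromosome into a handful of giant clusters.  The conventional
3-sigma rule admits ≈ 0.1% of null bin pairs; those rare false spatial
links are absorbed by the SCH intersection (zero spurious SCHs observed
over the planted test battery).  `"mean"` and `"constant"` cutoff policies
remain available.

### Signature statistics

Substitutions are typed as ordered ref>alt pairs on the + strand — 12
classes, no pyrimidine collapsing — in fixed lexicographic order (A>C is
type 0).  The complementing score of a 12-vector of counts is
`1 − 2·Σ_pairs min(n_x>y, n_y>x) / N` over the six direction-reversed
pairs: 0 iff counts are balanced within every pair, 1 when no complement
of any observed type occurs.  It is invariant under swapping the two
counts of any pair.  This is the simplest statistic consistent with the
stated behaviour of the score (bounded, "lower = more complementary",
pooled background defined the same way); the per-SCH scores are compared
to the pooled-over-all-SCH-genes background by a Z-test on the SCH-score
mean.

### Flank conservation

Windows are 21 reference nucleotides centered on the mutated base
(position 11); windows overhanging a contig, containing non-ACGT
characters, or whose center disagrees with the recorded reference allele
are dropped and counted.  Because all windows are anchored on the
mutation, "alignment" is positional — no gaps can occur.  Conservation is
the mean per-column Shannon entropy in bits (0 = identical, 2 =
i.i.d.-uniform limit), computed on raw frequencies without pseudocounts,
including position 11 (configurable).  The background test is
**size-stratified**: the entropy of a window group depends strongly on its
size (two random windows average ≈ 0.75 bits; large random groups approach
2), so each SCH is standardized against its own size-matched resampled
background, z_i = (s_i − μ̂_i)/σ̂_i, and combined as Stouffer
Z = Σ z_i / √k.  Pooling raw background scores across group sizes instead
makes the background SD meaninglessly wide.  Negative Z means conserved.

### Enrichment, drivers, CTCF

The hypergeometric tail P(X ≥ r) is exact (no binomial approximation);
the universe N is the full annotation, not the union of pathway sets.  A
cluster's p is the raw minimum over pathways — no multiple-testing
correction, so cluster p-values are comparable *between* datasets (DB vs
Hi-C vs SCH) but are biased low in absolute terms; coverage counts each
cluster only toward its argmin pathway.  Driver percentages use
two-proportion z-tests.  CTCF profiles average coverage-weighted
piecewise-constant signal in 50 bp bins over ±5 kb around each TSS
(minus-strand profiles mirrored; track gaps count as 0); the SCH/background
comparison tests per-TSS window means, the unit of observation being the
gene.

## The synthetic-data generator

The generator emulates exactly the statistical structure the pipeline is
designed to detect, with every source of randomness derived from one seed
(named child streams; identical config ⇒ byte-identical files):

* **Contacts**: Poisson counts around `depth·(d+1)^(−α)` (defaults
  depth = 100 expected counts on the diagonal, α = 1), as Hi-C counts are
  read counts; planted blocks multiply the mean by `contact_boost` before
  sampling.  A planted hotspot's block spans at least
  `hotspot_block_bins = 12` bins (≈ 0.5 Mb at 40 kb — TAD scale), with the
  member genes in distinct bins inside it; co-mutation hotspots are
  domain-level events, not single-bin events, and sub-TAD blocks would
  anyway sit below the correlation noise floor of a 250-bin chromosome.
* **Cohort**: per sample, each hotspot "fires" with probability
  `comut_prob` (default 0.8), mutating every member gene once; background
  genes mutate independently (default 0.02/sample).  Hotspot genes mutate
  *only* through hotspot events, so within-hotspot sample profiles are
  identical — the cleanest realization of "co-mutated at least once" and
  the reason the selected Hamming threshold is typically 1.0 on planted
  data.  A firing gene uses its fixed mutation site and the hotspot's
  substitution type with probability `signature_concordance` (default
  0.8), otherwise a random in-gene position with a random substitution
  (uniform over the 12 types because the reference is i.i.d. uniform).
* **Hotspot types** cycle through a fixed ordering in which consecutive
  hotspots get direction-reversed types (A>T, T>A, C>G, G>C, …), so any
  run with ≥ 2 hotspots has a complementary pair across hotspots — the
  pooled background is then genuinely more complementary than any single
  hotspot, which is the contrast the complementing Z-test targets.
* **Reference/flanks**: chromosomes are i.i.d. uniform A/C/G/T (no N);
  each planted gene's site carries its hotspot's reference base, and with
  probability `flank_conservation` (default 0.8) the whole 21-nt window is
  the hotspot motif.
* **Tracks and sets**: log-normal CTCF baseline (σ = 0.5) on 200 bp
  intervals, ×`ctcf_boost` (default 3) within ±2 kb of planted TSSs;
  80% of hotspots are embedded whole in one pathway among 20 sets of ~15
  genes; drivers hit 50% of planted and 5% of background genes.

**What it does not emulate** — and hence what green tests do *not*
establish about real data: read-level Hi-C biases (no ICE/KR balancing is
implemented or needed for Poisson-clean matrices), trinucleotide-context
mutational processes (SBS96), tumor subclonal structure, indels/CNVs,
gene-length and replication-timing covariates of mutation rate, and real
TAD/compartment hierarchy (planted blocks are flat).  Passing the battery
means the statistics behave correctly under their own model assumptions;
it does not validate the biological findings on real cohort-scale data.

## Problem sizes and calibration configurations

The planted reference scenario is the generator default: 2 chromosomes ×
250 bins at 40 kb, 300 genes, 40 samples, 5 hotspots of 4–8 genes,
boost 5, co-mutation 0.8 vs background 0.02.  Null calibrations run on a
reduced geometry (2 × 100 bins at 5 kb, 100 genes, 30 samples, background
rate 0.1) chosen so that hundreds of replicates complete in seconds while
each replicate still yields hundreds of co-mutated pairs for the paired
test's asymptotics.  The fully null cohort is generated with *no* planted
hotspots: rate-matched but jointly-firing, block-co-located hotspots are
weak real structure, not noise, and make an intra/inter "null" reject
through distance decay alone.  Unboosted planted groups are kept only for
the CTCF and conservation group-level calibrations, where gene grouping
must exist but carries no signal.  Measured rates: proximity rejection
≈ 2.5–4% at α = 5% (the paired test is mildly conservative because a
pair's own contact contributes to its background mean), CTCF ≈ 3–6%,
fixed-threshold intra/inter 0/200.

## Numerical and degenerate-case conventions

* Zero-variance t-tests: identical constant populations give p = 1
  (t = 0); constant populations with different means give p = 0.
* All-zero Jaccard pairs are undefined and excluded with a warning; the
  complementing score of a zero count vector raises.
* b_overall(d) with no unmasked entries is NaN ("undefined"), never 0;
  normalized entries at such distances stay flagged.
* d = 0 (same-bin gene pairs) uses the raw diagonal and participates in
  backgrounds.
* Background resampling and report generation draw from generators seeded
  by the run seed; reports serialize with sorted keys so byte-identity is
  meaningful.

## Known limitations

* The min-p threshold selection makes the downstream intra/inter p-value
  anti-conservative (≈ 3.5% null pass rate at α = 0.005); a selection-aware
  correction (e.g. max-t resampling) is future work.
* Inter-chromosomal contacts are out of scope; DB clusters may span
  chromosomes but only same-chromosome pairs ever contribute contact
  statistics.
* The conservation entropy score ignores phylogenetic conservation; it
  measures within-cohort sequence identity only.
* With very small cohorts the selected threshold can sit at 1.0 with many
  singleton clusters; all downstream stages handle this but power is low.
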