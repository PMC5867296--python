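# Methods

## Model and assumptions

`morphrank` ranks candidate genes for a functional term by
module-partitioned co-expression. The underlying assumptions are the
standard guilt-by-association ones: genes acting in a common process are
co-regulated across conditions, and that co-regulation is visible as
Pearson correlation within co-expression modules of at least one
available dataset/clustering configuration. The module partition matters:
correlating a candidate against *all* baits genome-wide dilutes signal
when a large bait set contains only pockets of strongly co-expressed
genes, whereas restricting both the bait context and the candidate pool
to one module isolates exactly those pockets.

Scoring, per configuration (dataset + clustering):

* Only modules containing at least `min_baits_per_module` baits are
  scorable (default 1 — a single bait suffices; no floor is inherent to
  the method, and raising it trades coverage for robustness).
* Candidate raw score = mean Pearson r with the in-module baits. Constant
  expression rows (SD < 1e-12) are defined to correlate 0 with
  everything.
* z-standardization is computed over each module's candidates only — not
  genome-wide and not including baits — because the purpose of the
  z-score is to make ranks comparable *across* modules whose raw
  correlation scales differ. A degenerate module (candidate raw-score
  SD < 1e-12) assigns z = 0 to all its candidates rather than ±∞.
* Pooled candidates are ranked by z descending; ties break
  lexicographically by gene id, which is deterministic and
  data-independent. Bait genes, unclustered genes, and genes in
  bait-free modules receive no score.

Model selection runs leave-one-out cross-validation: each bait is removed,
re-scored as a candidate, and its self-rank collected. The self-rank curve
plots, against a rank threshold t, the fraction of baits with self-rank
≤ t; its area (AUSR) is

    AUSR = (1 / (|G| · r_max)) · Σ_i max(0, r_max − r_i + 1),

so AUSR = 1 means every left-out bait was re-ranked first and AUSR = 0
means no bait re-entered the top r_max. A left-out bait that cannot be
ranked (unclustered, absent, or its module retains no bait) counts as
UNSCORED and contributes 0 — dropping such baits instead would inflate
the score of poorly covered bait sets. The configuration maximizing AUSR
wins; ties resolve to input order. Each configuration's LOOCV is computed
independently (no information sharing). The threshold ceiling r_max
defaults to 1000 and is exposed as a parameter; it fixes how deep into
the ranking a self-rank still earns credit.

A note on orientation: the self-rank curve is sometimes described as the
proportion of baits ranked *worse* than the threshold, which would make
small areas good. We use the proportion ranked at-or-better, under which
1 is a perfect score, consistent with how the AUSR is used for model
selection and reported here.

## Bulk mode

* **Job filter.** A term is analyzed iff at least one dataset contains
  ≥ 5 of its genes ("all datasets too small" discards). One adequate
  dataset suffices because model selection can choose it.
* **Permutation null.** For each size S on the 5–30 grid, n random bait
  sets (default 1,000) are drawn — dataset chosen uniformly at random,
  then S distinct genes from that dataset's pool — and run through the
  *full* algorithm, model selection included, recording the AUSR. The
  text describing the original procedure leaves open whether random runs
  used full model selection; we run it because observed terms do, and a
  null computed under a different procedure would not be exchangeable
  with them. Each (size, replicate) uses an RNG stream derived from
  (seed, size, replicate), so parallel and serial execution agree. The
  pool defaults to the whole genome; an annotated-genes pool is a flag
  (the two give indistinguishable nulls on synthetic data, which the test
  suite checks by a two-sample KS test).
* **Empirical p.** p = #(null AUSR > AUSR*) / n with *strict* inequality,
  so a term beating every permutation reports p = 0.00 (no pseudocount
  by default; a (count+1)/(n+1) variant is a flag on
  `empirical_pvalue`). Sizes outside the grid clamp to its ends —
  conservative above 30, since larger random sets score lower by chance
  in that regime. We take S = the number of baits present in the chosen
  configuration, since null sets consist entirely of present genes.
* **Multiple testing.** Benjamini–Hochberg per annotation source (GO and
  MapMan are corrected separately, as their term counts are reported
  separately); implemented via statsmodels, cross-checked in tests
  against a hand-coded step-up.
* **Products.** Extended annotations: terms with q < 0.05 contribute
  every candidate with z > 1.96 (the 97.5th standard-normal percentile)
  as a new gene→term assignment. Storage records: terms with p < 0.10
  keep their top-100 candidates with z > 1.28 (90th percentile). Both
  thresholds are strict and exposed as parameters; the two-decimal
  percentile values are used literally so the strict-inequality boundary
  behaviour is exact.

## Comparative networks

Per-species record tables are joined through orthogroup membership. A
candidate node is included iff its gene family contains, in a different
species, another candidate for the same term — or a bait gene, when
bait partners are enabled (the default; disabling reproduces the stricter
candidates-only display rule). Candidates connect to one bait-set hub
node per (species, term); included cross-species same-family candidate
pairs receive orthology edges. Bait genes themselves are never emitted as
nodes, and hubs appear only for species with included candidates (no
orphans). Family membership is exported as a node attribute rather than
nested compound-graph structure, keeping node-link JSON and GraphML
exports simple and lossless. Node and edge order in exports is sorted
(species, hubs first, gene id), so identical networks serialize to
identical bytes. Regulatory classes (TF, kinase/receptor, transporter,
other, unknown) come from case-insensitive keyword rules over gene
descriptions; the rule list is a parameter and can be loaded from YAML.

## Preprocessing

* **Variance filter.** Keeps the ceil(f·n) genes with the largest
  *sample* standard deviation (ddof = 1), f = 0.75 by default; ties at
  the cutoff keep the lower row index. Exact ceil makes "≈75% retained"
  deterministic.
* **Quantile normalization** (microarray): every column mapped onto the
  per-rank mean of the sorted columns; ties receive the mean of the
  reference values over their tied ranks. Idempotent; a single-sample
  matrix is passed through with a warning.
* **TMM** (RNA-seq counts): reference column = upper-quartile closest to
  the mean upper-quartile; per-pair M/A on genes positive in both
  columns; 30% (M) and 5% (A) rank-window trims per tail;
  factor = 2^(inverse-variance-weighted mean of remaining M); factors
  rescaled to geometric mean 1; output log2(CPM/factor + 1). Precision
  weights use library-relative counts p = x/N, w = (1−p_j)/p_j +
  (1−p_r)/p_r: this is proportional to the usual count-based weights
  whenever library sizes are equal, and — unlike the count-based form —
  makes the factors exactly invariant to rescaling any single sample,
  which is the normalization's defining property. All four constants
  (trims, reference quantile, log offset) are parameters. The test suite
  cross-checks the factors against the Bioconductor edgeR implementation
  on an equal-library-size fixture.
* Default order is normalize-then-filter; a flag swaps it (the
  alternative order is defensible and the literature does not fix one).
* Clustering solutions are an *input* (any external algorithm may
  produce them); a row-standardized k-means (scikit-learn) is bundled so
  the pipeline runs end-to-end without external software. Unclustered
  genes can never be scored in a configuration, but still count as
  present for the job filter.

## Synthetic compendia

The generator plants M modules of G genes: per dataset, module m draws a
latent sample profile f_m ~ N(0, I); a member gene is
√ρ·f_m + √(1−ρ)·σ·ε with ε ~ N(0, I), so at σ = 1 (the default) the
expected within-module Pearson correlation is exactly ρ — the latent
factor construction was chosen precisely because it makes this
expectation analytic, enabling calibrated tests. Background genes are
pure noise and unclustered in the truth partition. Annotations split
each module into baits and held-out true candidates (the missing-gene
scenario) plus uniform random terms with sizes on the 5–30 null grid.

What the generator does *not* emulate: platform artifacts (probe
saturation, library-size gradients beyond what TMM tests need), batch
structure, overlapping or hierarchically nested pathways, and hub genes
shared between modules. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated model, not
performance on any real compendium.

## Problem sizes and measured behaviour

The test suite and the acceptance script size their simulations for a
single CPU: null calibration uses a 300-gene pure-noise compendium
(ρ = 0.01), a null of 200 (tests) or 100 (script) replicates per size
5–30, and 200 random terms; recovery uses 20 (tests) or 10 (script)
seeds of a 300-gene ρ = 0.9 compendium clustered by k-means with
k = 12 — deliberately not the truth partition, so candidate pools mix in
background genes and recall@100 is a non-trivial measurement. Under the
null the fraction of terms at p < 0.05 lands within the binomial band
around 0.05; under planting, held-out recall@100 is ≈ 1 and coherent
terms outscore size-matched random terms in every seed.

## Known limitations

* Pearson correlation only; no rank-based or mutual-information option.
* No integration of protein–protein interaction or other network data
  into scoring.
* Empirical p-values have resolution 1/n; at the default n = 1,000 the
  smallest nonzero p is 0.001, and p = 0.00 means "better than every
  permutation", not p = 0.
* BH correction across annotation sources jointly is not offered.
* Very small bait sets (< 5 present genes anywhere) are never analyzed,
  by design.
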