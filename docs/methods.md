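# Methods

This note records the models and procedures implemented in `mirmod`,
the numerical choices behind them, what the synthetic benchmark does
and does not show, and known limitations.

## Preprocessing

Tumor expression is expressed per feature as a log2 ratio against the
mean of the unmatched normal samples (subtraction for log2-scale
input, log2 of the quotient for linear input). Differential expression
is a two-sided one-sample *t*-test of each gene's ratios against 0 —
the ratio matrix's natural null — at raw p < α (default α = 0.001) or
Bonferroni-corrected p < α. A two-sample pooled-variance mode (tumor
vs normal intensities) is available via the `normal=` argument for
users who prefer the classical contrast; the one-sample form is the
default because the pipeline's working object is the ratio matrix.
Zero-variance genes are excluded (the statistic is undefined).
Surviving rows are z-scored with ddof = 1; z-scoring is idempotent and
invariant to per-row affine maps, which also makes every downstream
correlation statistic identical whether computed on ratios or z-scores.

## Biclustering

The z-matrix defines a bipartite graph: gene g and sample s are
connected iff |z[g,s]| ≥ `z_threshold` (default 1.5; the field's
"changes significantly" has no canonical numeric value, so the
threshold is exposed in config). Edges carry weight |z| and the sign
of the change. A candidate module (G′, U′) is scored

    score = Σ_{g∈G′} [ max(W⁺_g + λC⁺_g, W⁻_g + λC⁻_g) − λ·|U′| ]

where W±/C± are the weight sums and counts of the gene's positive and
negative edges inside U′ and λ (default 1.0) is the penalty per absent
gene–sample pair. The inner max enforces per-gene sign consistency:
edges disagreeing with the gene's dominant direction count as absent.
This additive score is a deliberate simplification of likelihood-based
bicluster weights; the permutation test downstream is the significance
gate either way, and externally produced biclusters can be injected
through the module TSV adapter.

Search: one seed per gene (the gene plus its incident samples), grown
by steepest-ascent over single gene/sample additions and removals
while the score strictly increases. On matrices small enough to
enumerate (≤ 10 genes and ≤ 8 samples) the search switches to
exhaustive enumeration over all gene × sample subsets, so it is exact
there by construction; the greedy path is validated separately by
planted-block recovery. Candidates are ranked by score and admitted
while their gene-set Jaccard overlap with every kept module stays at
most 1 − `overlap_factor` (default 0.5; gene sets only — reported
overlap statistics concern genes and miRNAs, not samples).

## Permutation significance

For each module, N random modules of the same gene and sample counts
are drawn and the module's average off-diagonal pairwise Pearson
correlation is compared against theirs:

    p = #{ i : module_avg < random_avg(i) } / N

with strict inequality (p = 0 is attainable; no +1 correction, by the
indicator definition). Because modules share genes, random cohorts can
be built to reproduce the observed pairwise intersection sizes: random
sets are constructed in cohort order, each first drawing the observed
intersection count from every earlier random set, then filling
independently. Both genes and samples are resampled. Modules pass at
BH q < 0.05. Defaults: N = 1000, overlap matching on.

## Network expansion

Genes adjacent in the interaction network to at least one module gene
are candidates. They are ranked once by average PCC to the module
genes over the module samples (ties broken lexicographically) and
admitted in order while the module average strictly increases; the
walk stops at the first failure, reading the stopping rule literally.
Zero improvement is a rejection. A refresh mode (re-rank after each
acceptance) is available behind a flag. The sample set never changes,
and expansion can only raise the module average.

## miRNA selection

Candidates are the top T% of miRNAs by mean |Spearman| correlation
with the module genes over the module samples (rank correlation damps
outliers; minimum one candidate; default T = 3). Selection walks the
ranking greedily: every module gene receives the full selected miRNA
set as parents of a linear-Gaussian conditional fitted by OLS with
intercept, σ² is the ML residual variance RSS/n clamped at 1e-6 (a
perfect fit otherwise sends the likelihood to +∞), and the per-gene
log-likelihood is the Gaussian plug-in −(n/2)(log 2πσ² + 1). The
network score in the default mode is

    bic = logL − log(M)/2,    M = #genes + #miRNAs,

the form defined with the model (the undefined O(1) term is dropped);
`standard` mode replaces the penalty with (k/2)·log n, k = total
fitted parameters (per gene: intercept, one coefficient per parent,
one variance), for users wanting the textbook criterion — the default
penalty grows only logarithmically in the variable count and accepts
regulators much more liberally. A miRNA is accepted iff the score
strictly increases; the walk stops at the first rejection; modules
ending with fewer than two miRNAs are discarded as unable to express
combinatorial regulation. Likelihoods use the module's samples (the
module defines the regulatory context); an all-samples mode exists
behind a flag. ML variance (not unbiased) is used throughout,
consistent with likelihood scoring.

## Validation

All enrichment tests are upper-tail hypergeometric, p = P(X ≥ x) for
X ~ Hypergeom(N, m, k), computed over the universe of all measured
genes (not only DE genes). Four regulation-evidence cases are
implemented: predicted miRNA targets restricted to anti-correlated
pairs and tested for enrichment among module genes; experimentally
confirmed direct pairs (reporter-assay class) reported per se;
TF co-regulation, requiring target-set enrichment plus same-sign
TF–gene and TF–miRNA correlations; and miRNA→TF→gene chains, requiring
a negative miRNA–TF correlation with the TF→gene sign unconstrained.
Correlation sign constraints use Pearson over the module samples.
Pathway enrichment drops sets with more than 300 genes in the universe
(too general), applies BH within each module across its tested sets,
and reports q < 0.05; miRNA/TF evidence is reported with raw p.
Cancer-annotation ratios are plain fractions |members ∩ list|/|members|
and module overlap is the Jaccard index.

## Subtype assignment

Samples are clustered by average linkage on 1 − PCC over the most
variable genes (default 1000). Clusters are extracted by a dynamic
cut: cut heights are scanned from the root and a finer partition is
accepted while every cluster keeps `min_cluster_size` members
(default 30) **and** is internally cohesive — its own root merge
height at most 0.9× the cut height. The cohesion condition is this
package's addition: a pure size rule happily splits homogeneous noise
whenever a size-admissible split exists. A cluster is labelled with a
subtype when its markers deviate from the out-of-cluster samples in
the expected direction (two-sample *t*-test, p < 0.05) for a
configurable majority of the panel (default: all markers); clusters
matching zero or several subtypes stay unassigned. A module is
associated with a subtype when its samples' marker expression differs
from the other subtypes' cluster samples in the expected direction for
more than half of the panel — the laxer majority reflects that real
marker panels are rarely unanimous.

## Copy-number extension

Segments (1-based inclusive input, converted to 0-based half-open) are
averaged into fixed-size bins (default 1 Mb) per sample with
length weighting; entries with |ratio| below 0.2 are zeroed and
all-zero regions dropped. A region is associated with a module when
the Pearson correlation between its per-sample values and the module's
mean gene expression over the module samples reaches `pcc_threshold`
(default 0.3, matching the magnitude of reported exemplar
correlations); module genes whose start coordinate falls inside an
associated region are listed as cis candidates.

## Synthetic data

The generator emulates a two-platform tumor/normal microarray study.
For a planted module with effect size e and r regulators, each block
sample carries a latent activity u from a two-level mixture — 0.8 e
(moderate) or 1.6 e (strong, probability 1/3) with a 0.1 e
within-level spread — plus one standard-normal factor f_j per
regulator with loading g = 0.2 e. Planted miRNAs are negative linear
functions of their slice of the signal, y_j = β_j (u + g f_j) + ε with
β_j ~ N(−1, 0.2), and genes follow the average of the regulator
signals, x = u + (g/r) Σ f_j + ε with observation noise sd 0.3. Three
properties of this construction matter:

* the two-level latent keeps every block sample clearly above the edge
  threshold (so the bicluster retains whole sample sets) while holding
  the latent variance stable across realizations — with a Gaussian or
  heavy-tailed latent, the sample selection truncates exactly the
  variance the ranking and scoring statistics rely on;
* the gene loading g/r makes the gene signal exactly reconstructable
  from the full regulator set, so each regulator carries factor
  variance the others cannot explain and the saturated model leaves no
  shared residual for decoy miRNAs to absorb;
* planted gene rows carry a pan-tumor baseline shift (default 0.6, in
  proportion to e) so they are differentially expressed cohort-wide,
  as disease genes selected by a DE screen are; row centering makes
  the shift invisible to z-scores and every correlation.

miRNA measurement noise on planted rows is 0.05 (the regulator rows
are treated as well-measured); decoy miRNAs and all background cells
are N(0, 0.3). Everything scales with e, so e = 0 yields exact null
data. TF plans add expression rows following a module's mean signal
with dedicated co-regulated miRNAs (co-regulation case) or a repressor
record from a module regulator (chain case); the copy-number plan adds
dosage segments proportional to the module signal. The manifest
records every planted truth; `score_recovery` matches found modules to
planted ones by gene Jaccard (threshold 0.25) and reports precision,
recall and exact regulator-set flags.

What passing the benchmarks does and does not show: the generator's
blocks are cleanly separated, its noise is Gaussian and homoscedastic,
its regulators act linearly and its tables contain no systematic
biases, so recovery here demonstrates the machinery is correct and
calibrated — not that real cohorts, where effects are weaker and
confounded, would yield comparable recall.

## Benchmarks

`mirmod.benchmarks` fixes two experiments. The **recovery benchmark**
plants two 15-gene × 20-sample modules (effect 2.5, three regulators
each, coefficients −1 ± 0.2, noise sd 0.3, 20 decoy miRNAs) in an
80-gene × 300-sample cohort and runs the full pipeline with T = 100%
and standard scoring over 50 seeded replicates; it reports the mean
planted-gene recall and the fraction of planted modules whose
regulator set is recovered exactly (pooled per-module fraction, the
natural generalization of the single-module selection check; the
stricter every-module-per-replicate rate is reported alongside). The
**null calibration** generates 100-gene × 60-sample datasets with
effect 0 and runs biclustering plus the permutation test (200
permutations) directly on the z-scored matrix — a DE screen on null
data retains nothing, so it is skipped by design — recording the
fraction of modules at q < 0.05 and pooling permutation p-values of
uniformly random modules for a KS uniformity check (the discrete
p-value lattice is half-step-shifted onto the continuous uniform).
Problem sizes (300-sample cohorts, 50 replicates, 200 permutations,
20 null seeds) were chosen as the smallest at which the statistics of
interest are stable.

## Known limitations

* The bicluster score is additive, not likelihood-weighted; heavy
  hashing heuristics of the original bipartite-graph implementations
  are out of scope, and the greedy search carries no optimality
  guarantee beyond enumerable sizes.
* The permutation null compares a module selected for coherence
  against unselected random modules; on data with structure this is
  anti-conservative in principle, which is why the q-gate is the
  significance criterion rather than the raw p.
* Greedy forward selection with a stop-at-first-rejection rule is
  order-fragile: a decoy ranked above a true regulator ends the walk.
  With ~20 samples per module the marginal evidence for a third
  regulator is genuinely small, and a few percent of benchmark modules
  lose a regulator to this.
* Identifiers are opaque strings; no symbol mapping, genome build
  handling or probe summarization is attempted.
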