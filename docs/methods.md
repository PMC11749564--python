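# Methods

`bloomsex` reconstructs, at desk scale, the computational chain used to
detect a synchronized sexual-reproduction event in a diatom bloom from
metatranscriptomic time-series counts. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## The biological signal being modelled

Pennate diatoms such as *Pseudo-nitzschia* are heterothallic: sexual
reproduction starts when cells of opposite mating types (MT+ / MT−)
meet, typically once cell sizes have eroded below the sexualization size
threshold and densities are high (i.e. mid-bloom). In vitro, the onset
is marked by strong, short-lived up-regulation of a small panel of
genes — MRP1/MRP2 (MT+), MRM1/MRM2, the meiotic recombinase Rad51, the
endopeptidase cathepsin D, and an uncharacterized gene ("7488") —
followed over hours-to-days by a broad transcriptional shift
(photosynthesis, storage and pigment metabolism down; ribosome
biogenesis up). In a field time series this appears as (i) a small
gene cluster with a one-day log2FC spike of ~8, (ii) marker genes inside
that cluster, and (iii) a strong overlap between the spike cluster and
the genes up-regulated one hour after mating-type contact in vitro —
quantified by a Fisher odds ratio in the tens. The event-detection
verdict operationalizes exactly these three lines of evidence.

## Synthetic bloom generator

The generator (`bloomsex.simulate`) is first-class, tested code that
defines the study conditions for every downstream stage.

Counts for gene *g* in sample *j* are negative binomial with mean
`s_j · 2^(b_g + p_{k(g), d(j)})` and shape `1/α`, drawn via the
gamma–Poisson construction (which degrades continuously to Poisson as
`α → 0`):

* `b_g ~ N(6.5, 1.5²)` on log2 scale — median ≈ 90 reads per sample;
* `s_j` lognormal with log-sd 0.3, geometric mean 1 (library size);
* `α = 0.2` shared NB dispersion (per-gene fits estimate it back);
* `p` the planted cluster profile at the sample's day. Replicates
  within a day share the same expected profile, matching the later
  pooling-by-summation; an optional `extra_rep_log2_sd` knob adds
  between-replicate extra-dispersion (default 0, since the field data
  offer no estimate for it).

The default design is 10 sampling days × 2 replicates with phase
boundaries after days 3 and 7 (early / middle / late), 3000 genes of
which 1200 are differentially expressed across six archetypes:
middle-up, gradual monotone rise, early-high, early-high-with-late-
recovery, late-down, and a one-day spike of log2FC 8 on the first
middle-phase day. The spike cluster has 75 genes, 8 of which are
flagged as the marker panel (two MRP1 homologs, MRP2, two Rad51, two
cathepsin D, one 7488 homolog). Markers are ordinary spike-cluster
members distinguished only by their ids — marker detection is a
labelling exercise, not a distributional one. These sizes are the
study's own proportions scaled by roughly one seventh (8252 DE genes
and clusters of 75–2591 at full scale; the spike cluster is kept at its
actual size of 75).

Companion generators produce: BLAST-outfmt6-like hit tables whose
minimum-e-value ties and above-threshold e-values exercise the
consensus assignment rule, with a focal-species trajectory that
collapses on the final day (so the low-abundance sample exclusion
fires); GO annotations with a planted enriched term (odds ratio 10 in
the spike cluster by default) and nested subset terms (overlap
coefficient 1) for the redundancy collapse; an in vitro homology panel
in which each gene is mapped with probability 0.7 and per-timepoint
up/down labels are drawn with probabilities tilted on the odds scale so
the (cluster × label) table has a controlled expected odds ratio —
24 for (spike, T1, up) by default, echoing the magnitude seen in the
field comparison. The two label columns (cross vs MT+ and vs MT−) are
identical by default. Since the planting is probabilistic, every finite
positive target OR is attainable; OR ≤ 0 or baselines that push
`p_up + p_down ≥ 1` raise a configuration error naming the offending
cell. Environmental covariates (PAR, salinity, temperature,
fluorescence, turbidity, tidal amplitude) are smooth day-level trends
with small replicate noise.

What the generator does **not** emulate: read-level sequencing noise and
mapping ambiguity, compositional coupling between taxa, per-gene
dispersion heterogeneity, autocorrelated environmental forcing, and
many-to-many homology. Passing tests therefore demonstrate the
correctness and calibration of the chain under its stated model, not
robustness to those real-data features.

## Taxonomic profiling

A read is assigned at a rank only when *all* hits tied at the read's
minimum e-value agree at that rank and the minimum e-value passes the
database threshold (defaults 1e-70 for class-level 18S, 1e-30 for
genus/species rbcL). Ties are exact comparisons of the parsed decimal
e-values; bitscores never break ties. Relative abundances divide by the
taxonomically assigned reads per sample only. Samples whose focal-taxon
fraction falls below `min_focal_fraction` (default 0.05 — the source
analysis states no number, so this is a configuration value) are
dropped from expression analysis.

## Count conditioning

* **Coverage filter**: keep genes with ≥ 5 reads per day on average,
  where a day's coverage is the sum over its replicates (the boundary
  is kept). Under this day-sum definition the filter commutes with
  replicate pooling.
* **Size factors**: median-of-ratios over genes positive in all
  samples, normalized to geometric mean 1; total-count fallback (with a
  warning) if no gene is everywhere-positive.
* **Transform**: `X = log2(x/s + 1)` — a deterministic,
  dependency-free variance-stabilizing stand-in for a shrinkage-based
  regularized log. At bloom-scale counts the downstream statistics
  (PCA grouping, log2FC signs and ranks) are insensitive to the
  difference.
* **log2FC over median**: `log2FC_gi = X_gi − X−_g` with `X−_g` the
  transform (at size factor 1) of the gene's cross-condition *lower*
  median of raw pooled counts — an actually observed count, keeping the
  reference on the transform's domain, and making the median condition's
  log2FC exactly 0 at unit size factors.
* **PCA grouping**: centered PCA over samples; groups are taken from
  the sample sheet when present (authoritative), else seeded k-means
  on the first two components — a reproducible stand-in for grouping
  samples by eye on the ordination.

## Differential expression

Per gene, a one-factor NB GLM: `log μ_gj = log s_j + β_{group(j)}`.
Group means are exact score-equation solutions (Newton). The dispersion
starts from method-of-moments on normalized counts and is refined by
maximizing the Cox–Reid **adjusted** profile likelihood on a bounded
log-scale search (floor 1e-8, ceiling 50); the adjustment (−½ log det
of the weighted information) is the standard small-sample bias
correction for dispersion estimation after fitting means. No
empirical-Bayes shrinkage of dispersions or fold changes is applied,
and no independent filtering or outlier replacement — genes pass the
coverage filter upstream instead.

Contrasts are Wald tests `W = log2FC / SE`. The p-value uses a **t
reference with residual degrees of freedom** (n − number of groups)
rather than the normal: with per-gene dispersions estimated from a
handful of replicates, the normal reference ignores the estimator's
sampling noise and measurably inflates type-I error (0.125 at 3 vs 3
replicates under the null against a nominal 0.05, versus 0.052 had the
true dispersion been known); the t(n−p) reference restores calibration
(measured 0.047) at the cost of a little power at minimal replication.
This is the same consideration that leads quasi-likelihood F-tests and
moderated-t frameworks to finite-df references. Benjamini–Hochberg FDR
is applied per contrast (via statsmodels), and the DE set is the union
of genes at q ≤ 0.05 in any pairwise contrast.

## Profile clustering

DE genes are clustered on replicate-pooled per-day counts with an NB
mixture in which cluster k's parameter is a row-centered vector of
log2-scale condition effects `p_k` — the cluster's log2FC curve — and
each gene's abundance `q_g` is profiled out at its Poisson-score
optimum given the profile (`q_g = Σ_j x_gj / Σ_j s_j 2^{p_kj}`), so
clusters capture *shape*, not level. Dispersion α is shared across
clusters (a per-cluster flag would be a small extension; the source
analysis is silent).

Fitting is generalized EM: the E-step is exact; the M-step updates π in
closed form, each profile by bounded L-BFGS with the analytic gradient
`∂ℓ/∂p_m = ln2 (A_gm − w_m Σ_j A_gj)` where `A = r(x−μ)/(r+μ)`, and α
by bounded scalar search — each block move is accepted only if it does
not worsen its objective, so the observed log-likelihood is
non-decreasing at every iteration (asserted in tests). Initialization
is k-means on row-centered log2FC-over-median profiles; five
independent starts by default, best final likelihood wins. Stopping:
relative log-likelihood change below 1e-6 (about 0.07 loglik units at
the default problem size — far below any assignment-changing move;
poorly initialized starts otherwise creep monotonically for hundreds of
iterations before losing to the good starts anyway) or 500 iterations.
Hard assignments are argmax responsibilities with ties to the lowest
index. Gene order is immaterial (equivariance is tested).

Clusters whose profiles correlate above `r_min = 0.9` (Pearson) are
merged iteratively — highest correlation first, ties to the smallest
indices — with the merged profile refit by one weighted M-step. The
0.9 threshold is an explicit criterion replacing merging "by visual
inspection". K can be chosen by BIC
(`−2ℓ + params·log(n_genes·n_conditions)`) over a grid; the pipeline
default fits K = 8 and merges down.

## GO enrichment

Per (cluster, GO term): a 2×2 Fisher exact test of cluster membership
against term membership over the background of all annotated genes
(optionally all genes). Only terms with strictly more than
`min_de_in_go = 5` cluster genes are tested. The two-sided p sums
hypergeometric tables whose point probability does not exceed the
observed one (scipy's implementation; verified exhaustively against
enumeration for all tables with total ≤ 30). The odds ratio is `ad/bc`
with Haldane's +0.5 on every cell iff any cell is zero. BH-FDR is
applied per cluster, and counts are reported as `(a/|GO|)`. Significant
terms are then collapsed: an edge joins two terms when the overlap
coefficient of their *full* gene sets, `|A∩B|/min(|A|,|B|)`, exceeds
0.8; connected components are reported with the smallest-q member as
representative (ties: larger OR, then lexicographic id). No GO-DAG
ancestor propagation is performed.

## Cross-study comparison

The universe is the set of in situ genes with ≥ 1 mapped in vitro
homolog (gene-level "any homolog carries the label" semantics, against
either cross). For each cluster set, timepoint (T1 = 1 h, T2 = 24 h,
T3 = 5 d post-crossing) and direction, a 2×2 Fisher test yields the
odds ratio and p. Discordant genes are cluster members whose *mean*
homolog log2FC over the stated timepoints and both crosses opposes the
cluster's in situ direction (strictly > 0 for down-clusters, < 0 for
up-clusters); genes without homologs are excluded. Marker trajectories
are read directly off the log2FC-over-median matrix; markers absent
from the matrix are reported as not expressed.

## Event detection

"Transient" is formalized explicitly (the report labels the criterion a
stand-in for the visual call): a cluster is transient iff its profile's
maximum exceeds both adjacent observed sampling days by at least
`delta = 1.0` log2 units *and* every non-peak day sits within ±delta/2
of the non-peak median. The default is conservative relative to the
~8-log2FC spikes the markers show, and configurable. Neighbors are
adjacent observed days, not calendar days. The verdict is true iff a
transient cluster exists, ≥ 1 marker gene lies inside it, and its
cross-study T1-up association is significant at q ≤ 0.05; the three
flags are reported individually and the verdict is monotone in the
evidence.

## Constrained ordination

Canonical correspondence analysis, the vegan algorithm: chi-square
standardized response `Q = (P − rcᵀ)/√(rcᵀ)`, weighted centering and
standardization of the covariates, least-squares projection of Q onto
the weighted covariate space, SVD of the fitted matrix. Eigenvalues are
squared singular values; total inertia is `ΣQ²`; scores follow the
scaling-2 convention and axis signs are canonicalized (first non-zero
species loading positive). Collinear covariates are dropped greedily
left-to-right (earlier columns take precedence) with a warning and an
aliased list. Because correspondence analysis needs non-negative input
and the transformed expression matrix is signed, the response is
shifted by its global minimum first; the shift is recorded in result
metadata, and on simulated data the leading-axis sample ordering is
insensitive to it. Rainfall and nutrient covariates are excluded from
the default list.

## Problem sizes and runtime choices

The default simulation (3000 genes, 20 samples, 1200 DE genes) runs the
full pipeline in ~15 s. The repeated-seed properties (event detection
and verdict calibration over 50 simulated blooms each for signal and
null) use the default generator settings end to end. The dedicated DE
simulations use 2000 genes: 3 vs 3 for null calibration, 8 vs 8 (the
bloom's per-phase replication) for planted-effect recovery. Exhaustive
oracle checks cover all 2×2 tables with total ≤ 30 and 1000 random
p-vectors for the BH arithmetic.

## Known limitations

* The transform is not a shrinkage rlog; very low counts are stabilized
  only by the pseudo-count.
* Dispersion is estimated per gene with no information sharing; the
  finite-df t reference compensates for calibration, but power at 2–3
  replicates per group is accordingly modest.
* The mixture uses a single shared dispersion and no smoothness prior
  across days; profiles are free vectors.
* GO enrichment ignores the ontology graph (no ancestor closure).
* The CCA non-negativity shift is a convention, not a theory; axes
  should be read comparatively, not as calibrated gradients.
* The verdict thresholds (delta, q ≤ 0.05, ≥ 1 marker) are explicit
  operational choices; on real data they should be reported alongside
  the underlying flags, not consumed as a black-box boolean.
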