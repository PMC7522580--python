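# Methods

## The model

`lncsyn` infers a **signed lncRNA–miRNA synergistic interaction network**
from three sample-matched expression matrices (lncRNA, miRNA, mRNA) and
prior regulator→mRNA pair lists, then characterizes the network and fits a
two-lncRNA prognostic risk score. The inference has four steps:

1. **Prior evidence filter.** A regulator→mRNA pair enters the analysis
   when it is predicted by at least `min_programs` (default 3) target
   prediction programs *and* supported by at least `min_clip` (default 3)
   CLIP-seq datasets, or when it carries an experimental-validation flag.
   Duplicated pairs are merged keeping maximal evidence.
2. **Expression filter.** Each surviving pair is tested by Pearson
   correlation on the matched samples. p-values come from the exact t
   reference distribution with n−2 degrees of freedom and are
   Benjamini–Hochberg adjusted *within each testing family*. lncRNA–mRNA
   pairs are kept at adjusted p < 0.05 with either correlation sign;
   miRNA–mRNA pairs additionally require r < −0.4, reflecting the
   repressive miRNA–target relationship.
3. **Shared-target (co-regulation) test.** For a lncRNA regulating K mRNAs
   and a miRNA regulating n mRNAs out of a universe of N, the observed
   overlap k is referred to the upper tail of Hypergeometric(N, K, n),
   accumulated in log space. N defaults to the number of distinct mRNAs in
   the union of the two context-specific regulatory networks — the
   population actually regulatable in this context (configurable). Pairs
   with k = 0 are not tested: they cannot be co-regulated and would only
   inflate the BH family. Retention at adjusted p < 0.01.
4. **Synergy direction.** Each co-regulated pair's own lncRNA–miRNA
   correlation gives the edge: retained at raw p < 0.05 (an `adjust` flag
   switches to FDR), signed by the sign of r. The result is a strictly
   bipartite graph whose edges carry r, p and the shared mRNA set.

## Preprocessing

RNAs missing in more than `max_missing_frac` (default 0.3) of samples are
dropped. Remaining gaps are filled with the unweighted mean of the
`knn_k` (default 10) nearest RNAs by Euclidean distance over mutually
observed samples, restricted to donors observed in the target sample; if
fewer than k donors exist, all are used with a warning. Imputation is
deliberately a direct implementation of this rule rather than a library
imputer, because common implementations rescale distances by the observed
fraction and can rank neighbors differently. All values are then mapped to
log2(x + pseudocount), pseudocount 1 by default. Sample matching restricts
all matrices to the intersection of their sample sets, in the first
matrix's column order.

## Topology

- **Degree distribution**: least-squares line on (log10 k, log10 P(k))
  over observed positive degrees; gamma = −slope, with the fit's R². This
  matches the usual "scale-free R²" framing; it is not a maximum-likelihood
  exponent estimate and should not be over-interpreted.
- **Clustering**: a strictly bipartite graph has no triangles, so the
  standard global clustering coefficient is identically 0 (computed and
  warned about). Cohesion is instead measured by a 4-cycle coefficient:
  closed 3-edge paths / all 3-edge paths, where a path u–v–w–x is closed
  by the edge x–u; each 4-cycle closes four such paths. On K(2,3) this
  coefficient is exactly 1.
- **Mean path length**: average shortest-path length over connected pairs,
  pooled across components.
- **Null model**: degree-preserving double-edge swaps restricted to the
  bipartition (the miRNA endpoints of two edges are exchanged; signs
  travel with their lncRNA end; swaps creating duplicates are rejected).
  Default 10·|E| attempted swaps per replicate and 1000 replicates
  (200 inside `run_all` to keep full runs quick). Empirical p uses the
  add-one rule (1 + #extreme)/(R + 1), so p is never 0. A degree-preserving
  null was chosen over Erdős–Rényi because heavy-tailed degree sequences
  would otherwise dominate any metric comparison.
- **Centralities**: degree, pair-normalized shortest-path betweenness,
  and closeness with Wasserman–Faust component scaling (comparable across
  disconnected graphs).
- **Neighbor consistency**: a node is sign-consistent when ≥ 80% of its
  incident edges (boundary inclusive) share one sign.
- **Shared-count trend**: edges are grouped by shared-mRNA count, counts
  with fewer than 5 edges merged into the next count upward; the trend is
  the Pearson correlation between group centers and group means of
  −log10 p. With < 3 groups or zero variance the trend is NaN.

## Disease annotation and hubs

Enrichment of disease-labelled RNAs among network members of a class is
an upper-tail hypergeometric test against the candidate universe, which
defaults to the RNAs of that class present in the step-2 regulatory
networks. Centrality comparisons between annotated and other nodes use a
one-sided Wilcoxon rank-sum test ("annotated greater"); exact enumeration
for small tie-free samples, tie-corrected normal approximation otherwise.
Hubs are the ceil(top_frac · |V|) highest-degree nodes (default 10%),
ranked by (degree desc, id asc) so boundary ties resolve deterministically.
Composition ratios are rounded half-up to integer percentages. The
hub-induced subgraph reports hubs without hub partners separately.
Hierarchical views are display artifacts: root lncRNA → its synergistic
miRNAs (with disease flags) → the union of shared mRNAs → annotation
terms covering at least `min_term_count` (default 5) of those mRNAs. No
term-enrichment statistic is computed.

## Survival model

The Cox engine maximizes the Breslow partial likelihood for a single
covariate by Newton–Raphson with step halving (risk-set sums accumulated
once per iteration over time-sorted subjects), standard error from the
observed information, Wald z and two-sided p. Breslow ties were chosen as
adequate for continuous expression covariates. Convergence requires
|step| or |gradient| < 1e-10 within 100 iterations; fits with |coef| > 10
(hazard ratio beyond e^10 per unit) are reported as non-converged —
this is the signature of monotone likelihood under complete separation.

The risk score is Σ coefᵢ · expressionᵢ over the designated lncRNAs, with
coefficients from univariate fits on the training samples only (raw log2
expression, not z-scored). The cutoff is the median training score (even
n: mean of the middle two); samples strictly above the cutoff are
high-risk, the boundary is low-risk. The cohort is split 70/30, stratified
by event indicator with largest-remainder allocation so the overall
training fraction is hit exactly; the seed is recorded. Groups are
compared by the Kaplan–Meier product-limit estimator and the two-sample
log-rank chi-square (1 df). A `--resample` option repeats the split R
times and reports the fraction of significant test-set log-rank results.

## Synthetic data

The generator plants `n_modules` (default 20) co-regulation modules among
`n_lnc`/`n_mir`/`n_mrna` = 60/120/800 RNAs over 120 tumor + 30 normal
samples. Module m ties one lncRNA, one miRNA and 15 mRNAs to a latent
factor z_m ~ N(0,1): lncRNA = μ + z·signal_sd + ε, miRNA = μ + s_m·z·
signal_sd + ε, each mRNA = μ − (miRNA − μ_mir) + ε, with signal_sd = 1,
noise_sd = 0.5 and s_m = ±1 (half positive). The mRNA is built directly
anticorrelated with the miRNA so the r < −0.4 filter is satisfiable by
construction; at the defaults the planted miRNA–target correlation is
≈ −0.9 and the lncRNA–miRNA correlation ≈ 0.8·s_m. All other RNAs are
independent noise with matched variance; every regulator additionally
receives ~1% random background prior targets with mixed evidence counts,
so both the evidence filter and the correlation filter do real pruning.
Expression is emitted on linear scale (2^g − 1) with 5% injected
missingness so the full preprocessing path is exercised.

Tumor survival times are exponential with rate
baseline_rate·exp(β₁x₁ + β₂x₂) on centered covariates, where x₁, x₂ are
the log2 expression of the module-0 and module-1 lncRNAs, β = (0.5, 1.1)
and baseline_rate = 1/1000 per day. Censoring draws event ~
Bernoulli(1 − censor_frac) and backdates censored times uniformly on
(0, T), controlling the expected censoring fraction exactly. The second
risk lncRNA is shifted +1 log2 unit in tumor samples, emulating a
disease-upregulated gene. Disease labels are the planted node ids plus a
10% false-label fraction of background RNAs; per-module annotation terms
cover each module's mRNAs.

**What the generator does not emulate**: count-based noise (negative
binomial overdispersion), normalization artifacts, correlated module
overlap (each module contributes exactly one lncRNA–miRNA pair, so the
true network is a perfect matching), batch effects, or non-proportional
hazards. Consequences at the defaults: the inferred network has uniform
degree 1, so the power-law fit is undefined there; and every network node
is planted, hence disease-labelled, so annotated-vs-other centrality
comparisons degenerate. `run_all` records these as notices; the topology
and hub statistics are validated on constructed graphs in the test suite.
Passing tests therefore demonstrate correctness of each operation and
end-to-end recovery of planted signal, not performance on real tumor
cohorts.

## Numerical choices

- BH adjustment: step-up with stable mergesort; equal p-values receive
  equal adjusted values; capped at 1.
- Hypergeometric tail: logsumexp over log-pmf terms; k = 0 returns 1
  exactly; far tails stay positive below 1e-300.
- Perfect correlations (|r| = 1 after clipping) get p = 0.
- Zero-variance vectors raise a dedicated error in the scalar correlation
  path and yield NaN r / p = 1 in the vectorized path (such pairs are
  filtered before thresholding).
- Degenerate inputs: empty prior sets and empty networks propagate as
  empty outputs with warnings; an empty co-regulation result short-circuits
  the pipeline with an explicit notice; all-dropped expression is an error.

## Problem sizes

Defaults were chosen so a full synthetic run (simulate → preprocess →
network → topology → disease → prognosis) completes in a few seconds and
the whole test suite in well under a minute of compute per module family:
120 + 30 samples, 980 RNAs, ~2000 prior pairs, 1000 rewiring replicates
in the standalone null (200 within `run_all`). These are the package's
reference study conditions; they are not tuned per test.

## Known limitations

- Univariate screening ignores correlation between candidate prognostic
  lncRNAs; coefficients are attenuated when several true risk factors
  coexist (visible in the synthetic recovery: the second coefficient is
  estimated below its generating value when the first also drives hazard).
- The log-log least-squares power-law fit is biased relative to MLE and is
  provided for descriptive comparability only.
- The 4-cycle clustering null and the path-length null share one rewiring
  scheme; metrics on very sparse graphs (|E| < ~10) are noisy.
- GraphML serialization stores shared-mRNA sets as comma-joined strings
  (GraphML has no list attributes); ids containing commas are unsupported.
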