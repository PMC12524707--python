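# Methods

This note documents the statistical machinery behind `gmtrepurpose`: the
models and conventions each stage implements, the defaults and why they
were chosen, what the synthetic-data generators emulate (and what they
deliberately do not), and the numerical decisions made where the design
was genuinely open.

## Single-sample enrichment and the GMT score

The per-sample statistic is the rank-based ssGSEA running sum.  For
sample *j*, genes are ranked by expression descending (ties broken by
gene identifier, so the ranking is deterministic); position *i* of *N*
carries weight `(N - i + 1)^alpha`.  With `P_in(i)` the weighted
cumulative fraction of set genes encountered by position *i* and
`P_out(i)` the unweighted cumulative fraction of non-set genes, the
score is `ES = sum_i [P_in(i) - P_out(i)]`.  `alpha = 0.25` by default;
being rank-based, ES is invariant under any strictly monotone transform
of one sample's expression vector, which is why log-CPM suffices as the
count normalization (below).

The GMT score is `ES(mesenchymal) - ES(proneural)`.  An optional cohort
rescaling (divide all scores by the max-minus-min over samples and sets)
is exposed but off by default: the two scores are already on one scale,
and the downstream median split is invariant to it.  A kernel-density
CDF variant of single-sample scoring (as in the GSVA package) is a known
alternative; this package implements the ssGSEA statistic only, and all
cross-checks are property-based (hand-evaluated running sums, rank
invariance) rather than parity with any external implementation.
Gene-set scoring requires at least 2 set genes in the matrix by default
(`min_intersect`, lowered to 1 only in toy settings).

Median stratification sends samples strictly above the median to
"high", everything else (including ties at the median) to "low"; a
cohort with all-identical scores is rejected rather than split
arbitrarily.

## Two-group GSEA

Genes are ranked by signal-to-noise `(mu_A - mu_B)/(sd_A + sd_B)` with
each standard deviation floored at `0.2 * |mean|` (0.2 when the mean is
zero) — the classic GSEA stabilization.  The enrichment score is the
signed maximum deviation of the weighted KS running sum (hit weights
`|metric|^p`, `p = 1`; miss decrement `1/(N - m)`).  The null is
phenotype permutation when both groups have ≥ 3 samples, else random
gene sets of matching size.  NES divides ES by the mean magnitude of
same-sign permutation scores; nominal p is the same-sign tail fraction;
FDR q is the standard ratio of same-sign permutation-NES and
observed-NES tail fractions, clipped at 1.  The permutation stream is a
pure function of the seed.  Under a label-permuted null the empirical
type-I rate at nominal 0.05 stays inside the binomial 99% band (checked
with 200 sets and 1000 permutations in the acceptance suite).

## Co-expression modules

Unsigned adjacency `a_ij = |cor(x_i, x_j)|^beta`.  The pipeline preset
fixes `beta = 12`; `pick_soft_threshold` scans candidate powers and
selects the smallest whose connectivity distribution passes a
scale-free fit `R^2 >= 0.8`, where `R^2` is the squared Pearson
correlation between `log10` bin frequency and `log10` bin center over 10
connectivity bins.  A caveat documented here because it shapes the
tests: at high powers even unstructured data produces a right-skewed,
monotone-decaying connectivity histogram and can pass the fit index —
the index measures the shape of the degree distribution, not the
presence of modules — so the selection is most meaningful over low-power
ranges and on genuinely heterogeneous (heavy-tailed) structure.

The topological overlap measure and its dissimilarity `1 - omega` are as
defined in the README; modules come from average-linkage hierarchical
clustering with a *static* cut (height 0.995, minimum module size 30).
The dynamic hybrid tree cut used by the reference WGCNA implementation
is not reproduced: it has many interacting parameters that the analysis
does not depend on, while the static cut is fully specifiable and
recovers planted modules with Jaccard ≥ 0.8 at within-module correlation
0.8 (acceptance suite).  Unassigned genes carry label 0.

Eigengenes are the first right singular vector of the standardized
(zero-mean, unit-variance per gene) module block, scaled to unit
variance and sign-oriented so the mean correlation with member genes is
positive; a one-gene module degrades to the standardized gene with a
warning.  Modules merge when their eigengene dissimilarity `1 - cor`
clusters below 0.25 (average linkage); merging is idempotent and
monotone in the height.  Module–trait association is the Pearson
correlation of eigengene and trait across samples with a two-sided
t-test (n − 2 df); the GMT-associated module is the one with the largest
positive correlation with the GMT score.

## Differential expression

Library sizes are normalized with median-of-ratios size factors
(reference: per-gene geometric mean over samples, computed on genes
expressed everywhere; factors rescaled to geometric mean 1).  Per gene,
the negative-binomial dispersion is estimated by method of moments
within each condition, `alpha = (s^2 - mu)/mu^2`, df-weighted across the
two conditions.  With five replicates per group the per-gene estimate is
far too noisy for Bonferroni-scale tails — floored only at a tiny
constant it produces several familywise false positives per null run —
so each gene's dispersion is floored at the common (across-gene mean)
dispersion.  This deliberately conservative moderation restores
familywise error control (0 false positives in ≥ 95% of seeded null
runs at 2000 genes) while keeping sensitivity ≥ 0.9 for planted 4-fold
changes at `mu = 100`, `alpha = 0.1`, n = 5 + 5.

The Wald statistic is `log2FC / SE` with `log2FC = log2((mu_A + 0.5) /
(mu_B + 0.5))` (the 0.5 pseudo-count guards zero means; genes with a
zero-mean condition are flagged `half_shifted`) and the delta-method
variance `SE^2 = (1/ln 2)^2 [ (1/n_A)(1/mu_A + alpha) + (1/n_B)(1/mu_B +
alpha) ]`, referred to the standard normal.  Bonferroni correction runs
over tested genes only; all-zero genes are excluded from both testing
and the correction denominator.  Up-regulated genes satisfy adjusted
p < 0.05 and log2FC ≥ 1 (log base 2 throughout).  Dispersion shrinkage
toward a fitted trend, independent filtering and outlier replacement —
features of full DE frameworks — are intentionally out of scope; the
pipeline consumes only the up-gene list, and recovery/calibration
properties are the test surface.

## Network hub ranking

Edges are thresholded on confidence (strictly > 0.7, with the STRING
0–1000 scale auto-detected) and treated as unweighted.  The six
centralities are: Degree; MCC = sum over maximal cliques containing the
node of `(|C| - 1)!` (Bron–Kerbosch with pivoting); MNC = size of the
largest connected component of the open-neighborhood subgraph; EPC =
mean fraction of other nodes reachable under seeded Bernoulli edge
retention (retain probability 0.5, 1000 trials by default — the
published description of this metric is not fully specified, so this
definition is fixed here and both parameters are exposed); harmonic
closeness (sum of reciprocal distances; robust on disconnected graphs
where classical closeness is undefined); and radiality `(1/(n-1)) *
sum_w (diam_c + 1 - d(v, w))` over reachable `w`, with `diam_c` the
diameter of the node's component and unreachable pairs contributing 0.
With retain = 1 the EPC estimator is exactly fractional reachability,
which is how it is compared against brute force; at retain < 1 it is
checked against an exhaustive edge-subset expectation at Monte-Carlo
tolerance.

Per metric, nodes are ranked descending with average ranks on ties; the
composite score is the mean of the six ranks (lower = more central) and
the hub signature is the k best-scoring candidate genes (candidates:
the module ∩ up-gene intersection; missing candidates are dropped with a
warning, and k larger than the candidate pool degrades to the full
pool).  The compound–target–hub network reuses the same machinery with
compounds kept as isolated nodes when all their edges fall below the
confidence threshold.

## Survival

Kaplan–Meier estimation, the log-rank test and univariate Cox regression
are delegated to `lifelines` (Efron tie handling, Newton–Raphson on the
partial likelihood); the module owns the screening conventions.  The KM
median is the earliest time with S(t) ≤ 0.5 (undefined when never
reached).  The prognosis screen fits one Cox model per candidate gene on
expression, keeps genes with HR > 1 and Wald p < 0.05, then splits
samples at median expression (ties to "low", mirroring the GMT
stratification) and reports the log-rank chi-square and p.  Monotone
likelihoods are returned as flagged non-converged results rather than
raised.  Two classical identities anchor the tests: the fitted Cox
coefficient agrees with a grid/line-search maximizer of an independently
coded Efron partial likelihood to 1e-4, and the log-rank statistic
equals the Cox score test at beta = 0 for a binary covariate on tie-free
data.

## Connectivity map

Weighted-KS ES with hit weights `|z|^p` (`p = 1`, the usual convention
when no exponent is stated) and miss decrement `1/(N - m)`.  WTCS is
`(ES_up - ES_down)/2` when the two one-sided scores disagree in sign,
else 0; an up-only query (the pipeline's case — the hub signature has no
down component) uses `WTCS = ES_up`, and the down-set path is kept for
generality.  NCS normalizes WTCS by the mean magnitude of same-sign
values within each (cell line, perturbagen type) group; a degenerate
group yields NCS = ±1.  tau is the signed percentile of |NCS| against a
reference distribution; because the external reference panel is a
hosted database, the reference here is self-referential — all NCS values
computed for the same query across the loaded library — which preserves
the percentile semantics and the ≤ −90 reverser rule.  The per-compound
summary across cell lines is the more extreme of the 33rd and 67th
percentiles of the compound's taus (ties to the upper).  Reversers are
compounds with summary tau ≤ −90, reported most-negative first.

## Chemoinformatic funnel

Predictor outputs are consumed as score tables; the predictive models
themselves (BBB permeability platforms, P-gp substrate classifiers) are
external services and are not re-implemented.  The funnel order is fixed
— connectivity, BBB, literature co-occurrence, P-gp, similarity — and a
permuted order in the config is an error.  Two BBB rules are provided
because both appear in practice: scores on both platforms at least those
of a reference drug (temozolomide; "comparable" is implemented as ≥ with
an optional tolerance, default 0), or membership in the top-30 of both
platforms (descending, average ranks on ties, then compound id).  P-gp
requires a unanimous "non-substrate" call from three predictors.
Literature co-occurrence uses strict thresholds: > 3 articles for genes,
> 5 sentences for drugs.  Tanimoto similarity `|a AND b| / |a OR b|` on
equal-length bit fingerprints flags compounds within 0.7 of a reference
drug; two empty fingerprints score 0 with a warning.  Similarity and
co-occurrence are annotations in spirit, but compounds missing from a
required table are excluded from that stage's pass set (and carried with
an "unknown" verdict) so survivor counts stay honest.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their parameters and seed, and each
returns a ground-truth record sufficient to compute every recovery
metric without re-derivation.

*Cohort* (`gen_bulk_cohort`, defaults n = 200 samples × 400 genes): a
latent axis `g_s ~ N(0,1)` drives 25 mesenchymal genes (loading +1), 25
proneural genes (loading −1) and a 60-gene module (axis loading plus a
shared N(0,1) module factor), with N(0, 0.5²) gene-level noise and
i.i.d. N(0,1) background genes.  Survival is exponential with hazard
`0.001 * exp(0.5 * g_s)` per day under independent exponential censoring
at rate 0.0005 (roughly one-third censored) — chosen so Cox recovery has
a closed-form truth.  Expression is Gaussian because the enrichment and
co-expression stages are rank- and correlation-based, making the
marginal family immaterial.  In the coherent end-to-end study
(`simulate_all`) the mesenchymal genes additionally load 0.6 on the
module factor, so the mesenchymal program and the planted module form
one co-expressed block: with antagonistic ±1 programs alone, the
unsigned network clusters mesenchymal and proneural genes into a single
module whose eigengene sign is a coin flip (half the members correlate
negatively), and "the module most positively correlated with the GMT
score" would be unstable across seeds.  The overlap makes the
GMT-associated module well-defined, which is the situation the analysis
presumes.

*Counts* (`gen_counts`, defaults 2000 genes, n = 5 + 5): NB counts at a
common baseline mean 100 and dispersion 0.1, with planted genes shifted
4-fold in condition A.  A constant baseline mean is a simplification —
real libraries have mean–dispersion trends — so the calibration results
certify the test under correct NB sampling, not under trend
misspecification.

*Network* (`gen_network`, defaults 300 nodes, 20 hubs): preferential-
attachment background (m = 2) plus planted hubs wired to 30 random
background nodes each and to one another (an inter-hub clique); edge
confidences uniform in (0.71, 1.0), i.e. pre-thresholded.

*Library* (`gen_signature_library`, defaults 100 compounds × 9 cell
lines): inert perturbagens are N(0,1) everywhere; the 5 reversers are
shifted by −3 on the signature genes in every cell line (optional mimics
by +3).  Real perturbagen libraries have correlated noise, dose and
time structure, and cell-line-specific baselines; none of that is
emulated, so passing tests certify the scoring conventions and the
separation of a strong planted effect, not robustness to assay
artifacts.

*Chem tables* (`gen_chem_tables`): BBB scores, P-gp calls, co-occurrence
counts and fingerprints with a configurable pass pattern around a
temozolomide-like reference row scoring 50 on both BBB platforms.

What passing tests on these generators shows: the statistics are
implemented correctly (oracle parity), calibrated under their own
assumptions (seeded nulls), and able to recover planted structure at
realistic effect sizes.  What they do not show: performance on real
cohorts with batch effects, mean–variance trends, correlated gene sets
or weak effects.

## Numerical choices and degenerate inputs

Ties in expression rankings break by gene id; ties at the median go to
"low"; rank ties in centrality and BBB top-k use average ranks, then
compound/node id — every ordering in the package is deterministic.
Duplicate gene rows collapse by mean (order-independent).  Counts
normalization is log-CPM `log2(1e6 * c/libsize + 1)`, a documented
stand-in for variance-stabilizing transforms; downstream stages are rank
or correlation based, so any monotone variance-damping transform serves.
Eigengene sign orientation, the EPC definition, harmonic closeness and
the per-component radiality convention are fixed as described because
the upstream descriptions leave them open.  The Cox convergence
tolerance and iteration cap are lifelines defaults; non-convergence is
flagged, not fatal.  Known limitations: no blockwise processing for very
large gene sets (the TOM is dense), no multi-factor DE designs, no
multivariate Cox, and no attempt to reproduce external predictor or
reference-panel values.

## Problem sizes

Defaults throughout the tests and the acceptance script: cohorts of 200
samples × 400 genes, count experiments of 2000 genes × 10 samples,
networks of 300 nodes, libraries of 900 perturbagen profiles × 400
genes, 10 independent seeds for recovery metrics, 20 for coefficient
recovery, 1000 permutations for the GSEA null and 200–1000 Monte-Carlo
trials for EPC.  These sizes give stable Monte-Carlo estimates (binomial
99% bands, KS tests at alpha 0.001) while keeping a full run of the
suite and the acceptance script in the minutes range on one CPU.
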