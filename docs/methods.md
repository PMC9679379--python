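# Methods

`methscore` implements a complete expression-based subtyping and prognostic
scoring workflow for tumor cohorts, organized around the genes that write
(DNMT1/3A/3B), erase (TET1/2/3) and read (MBDs, ZBTBs, UHRFs, glycosylases)
the 5-methylcytosine (5mC) mark. This note documents the statistical
models, the defaults and why they were chosen, the synthetic-data design,
and the numerical conventions.

## Pipeline model

The workflow assumes a cohort of tumor samples with log2-scale expression
(genes × samples) and right-censored overall survival. Its chain is:

1. **Preprocessing.** Samples with unknown follow-up time, follow-up
   shorter than `min_days` (default 30; exactly 30 days is kept — the rule
   is a strict `<`), or unknown vital status are removed, with per-rule
   counts. Rows naming multiple genes (identifier containing `///` or `;`)
   are dropped; duplicate gene symbols are collapsed to the per-sample
   median. Per-gene z-scores use the population SD (ddof = 0), a fixed,
   configurable convention; zero-variance genes are dropped with a warning.
2. **Regulator landscape.** Mutation frequency is the percent of profiled
   samples (the full sample universe, not just mutated ones) with ≥ 1 call
   per panel gene; CNV gain/loss are percents of samples at or beyond the
   ±1 GISTIC-style thresholds. Two-group expression tests use the Wilcoxon
   rank-sum statistic — exact when the smaller group has ≤ 10 samples and
   the gene has no ties, otherwise the normal approximation with tie and
   continuity corrections. Correlation matrices are Spearman (default) or
   Pearson. Immune-cell/factor activity is summarized by generic signature
   scoring over user-supplied gene sets (mean z or ssGSEA), not by a
   deconvolution method: deconvolution is a distinct tool with fixed
   reference profiles, while signature scoring keeps the correlation
   analyses exercisable on any cohort, offline.
3. **Consensus clustering.** Monti-style resampling: each of `R` resamples
   (default 1000; the test suite and acceptance script use 100 for speed)
   draws ⌈0.8·n⌉ samples without replacement and partitions them with
   k-medoids on 1 − Pearson correlation over the z-scored feature genes
   (Euclidean available). The consensus matrix is co-clustering count over
   co-sampling count; an error is raised if any pair is never co-sampled.
   Final subtype calls cut an average-linkage tree of 1 − consensus at k;
   clusters are labeled 1..k by decreasing size. The number of clusters is
   recommended by the delta-area elbow of the consensus CDF (largest k with
   relative gain ≥ 0.1), with PAC = CDF(0.9) − CDF(0.1) reported and a
   low-confidence flag when PAC at the chosen k exceeds 0.2. Users may
   always override k.
4. **k-medoids.** Instances with at most 1000 medoid subsets are solved
   exactly by enumeration (ties to the lexicographically smallest set);
   larger instances use the deterministic PAM build + swap heuristic
   (greedy build; first-improvement swaps scanned in fixed medoid-index,
   candidate-index order). The split exists because PAM's single-swap
   neighborhood provably stalls at local optima on a noticeable fraction of
   tiny instances, where enumeration is cheaper anyway; at cohort scale the
   heuristic is the standard choice.
5. **Differential expression.** Per gene, a two-group linear model with
   empirical-Bayes variance moderation: the prior (d0, s0²) is estimated by
   moment matching on log s² via digamma/trigamma identities (with a Newton
   inversion of the trigamma function), the posterior variance is
   (d0·s0² + d·s²)/(d0 + d), and the moderated t is referred to a
   t-distribution on d0 + d degrees of freedom. Setting d0 = 0 recovers the
   ordinary pooled-variance t exactly. DEGs require raw p < 0.05 **and**
   |log2FC| > 1 (both strict, the conventional rule); BH-adjusted p-values
   are reported and can be used as the threshold instead. For k = 3
   subtypes the default contrast is cluster 2 vs cluster 3 (size-ranked
   labels), with an any-pair union mode available.
6. **DNA methylation score (DMS).** Candidate DEGs are screened by
   univariate Cox proportional-hazards fits — Newton–Raphson on the Breslow
   partial likelihood, Wald p — keeping genes at raw p < 0.05 regardless of
   direction. Kept genes are z-scored and decomposed by SVD; each sample's
   DMS is the sum of its scores on the first two principal components,
   DMS = σ₁·PC1 + σ₂·PC2. PCA leaves each component's sign arbitrary, so
   σ_m ∈ {−1, +1} is chosen to make the component correlate non-negatively
   with the mean z-expression of the *protective* screened genes (hazard
   ratio < 1); with that convention high DMS tracks protective expression
   and the high-DMS group is the longer-surviving one. With one usable gene
   the score degenerates to that gene's z (PC2 = 0, warned); a
   rank-deficient matrix likewise zeroes PC2. New cohorts are scored by
   standardizing with the *new* cohort's own means/SDs (robust to
   cross-platform scale shifts; a flag switches to stored training
   constants), projecting onto the stored loadings, and imputing missing
   screened genes at z = 0 — at least 80% of screened genes must be
   present.
7. **Survival.** Kaplan–Meier product-limit curves with Greenwood
   variance; median survival is the smallest time with S(t) ≤ 0.5
   (undefined if never reached). The k-group log-rank test uses the
   observed-minus-expected statistic with hypergeometric covariance.
   The optimal DMS cutpoint maximizes the absolute standardized two-group
   log-rank statistic over candidate cuts — midpoints between consecutive
   unique score values leaving at least a `minprop` fraction (default 0.1)
   of samples on each side; ties go to the smaller cut. Midpoints (rather
   than observed values) remove dependence on score granularity. Because
   the cut is *selected* to maximize the statistic, the naive p-value at
   the chosen cut is anti-conservative: results carry an explicit
   `selection_biased` flag, and an optional permutation-adjusted p-value
   (re-running the scan on permuted scores) is available.
8. **Enrichment.** GSEA uses the weighted Kolmogorov–Smirnov running sum
   (hits advance by |stat|^p over the in-set total, default p = 1; misses
   retreat by 1/(N−K); ES is the extremum by absolute value). Significance
   uses gene-set permutation — random same-size sets — because small
   cohorts make phenotype permutation unstable; phenotype permutation is
   available when a two-group design is supplied. NES divides ES by the
   mean |null ES| of the same sign; p-values are same-sign empirical with
   the +1 correction; BH FDR is applied across sets. Over-representation
   uses the exact hypergeometric upper tail. ssGSEA scores use the
   normalized integral difference of the rank-weighted in-set ECDF
   (exponent 0.25) and the out-of-set ECDF.

## Synthetic cohorts and what they do (not) show

`syndata.simulate_cohort` generates cohorts with full ground truth so every
stage is testable offline. Defaults mirror the cohort dimensions the
workflow was designed around: 143 samples, a 20-gene regulator panel,
3 latent subtypes, 1000 background genes of which 100 are true DEGs.

* **Panel structure.** Each regulator gets per-cluster mean offsets drawn
  once and standardized so clusters are separated by `cluster_shift`
  (default 2) noise-SDs per gene.
* **DEG block.** A fraction `deg_shared_frac` (default 0.7) of true DEGs
  follows one shared subtype-severity gradient — adjacent clusters one
  `deg_log2fc` step apart (default 2), random per-gene sign — so the block
  has a single dominant co-regulated axis, which is exactly the premise of
  a PC1+PC2 score ("the greatest block of highly correlated genes"). The
  remaining DEGs are up-shifted by `deg_log2fc` in an idiosyncratic random
  proper cluster subset. With fully idiosyncratic patterns the "first
  principal direction" of the block would be ill-defined (k−1 equally
  strong axes) and no PCA score could track it.
* **Latent prognostic score.** The standardized first-PC sample scores of
  the realized (z-scored) true-DEG block, sign-anchored to the block mean.
* **Survival.** Exponential event times with log h_i = log(baseline) −
  `surv_beta`·score_i (positive `surv_beta` ⇒ high score protective;
  baseline hazard 1/500 per day gives glioblastoma-like medians around a
  year). A Weibull option exists behind `surv_dist`. Censoring is an
  independent exponential whose rate is solved numerically (competing
  exponentials) so the expected censored fraction equals `censor_rate`
  (default 0.3).
* **Mutations / CNV.** Per-gene Bernoulli mutation calls (defaults:
  DNMT3B 19%, TET1 15%, DNMT1 12%, others 5%) and independent gain/loss
  CNV calls (10% / 15%, a quarter at the ±2 level).

Deliberately **not** modeled: negative-binomial count noise, batch
effects, CNV–expression coupling, gene–gene correlation beyond the planted
programs. Passing tests therefore demonstrate that the statistical
machinery recovers planted structure of the assumed form at realistic
sizes — not that any particular real cohort has such structure.

## Numerical conventions

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed gives byte-identical outputs (writers use a fixed float
  format).
* Cox fits: Newton–Raphson, step tolerance 1e-10, max 50 iterations;
  |β| > 50 or a non-positive information is reported as non-converged and
  the gene is flagged and excluded from the kept set, never silently
  dropped. Constant covariates are flagged the same way.
* Moderated-t prior: if the observed spread of log s² does not exceed the
  sampling spread, d0 = ∞ and every variance shrinks to s0² (normal
  reference distribution).
* Consensus matrices are symmetrized and the diagonal forced to 1 before
  CDF/PAC computation; PAC uses the off-diagonal upper triangle.
* Degenerate inputs raise informative errors: empty sample universes,
  all-identical scores, no events, k > n, sets disjoint from the ranked
  list, CNV codes outside {−2..2}.

## Known limitations

* The cutpoint scan is O(candidates × event times) in pure Python/NumPy;
  fine to a few hundred samples, not tuned for thousands.
* Gene-set permutation GSEA answers a different null than phenotype
  permutation; with few sets the BH FDR across sets is coarse.
* The Cox screen fits each gene marginally; correlated screened genes are
  expected (the PCA step is what aggregates them), so the screen's kept
  set is not an independent-discovery list.
* Subtype labels are arbitrary (size-ranked); all truth comparisons use
  the adjusted Rand index, and the DEG contrast between labels 2 and 3 on
  real data should be chosen by inspecting the clusters, not assumed.
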