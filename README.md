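# methscore

Consensus subtyping of tumor expression cohorts on a DNA-methylation
regulator panel, and a PCA-based **DNA methylation score (DMS)** that
stratifies survival.

## The problem

DNA 5-methylcytosine (5mC) is deposited by writers (DNMT1, DNMT3A,
DNMT3B), removed by erasers (TET1–3) and interpreted by readers (MBDs,
ZBTBs, UHRFs, glycosylases). The joint expression state of this ~20-gene
regulator panel defines methylation-regulation *patterns* that differ
between tumors and track prognosis and immune context. `methscore` turns
that idea into a reproducible pipeline for any cohort supplied as plain
TSVs (expression, clinical follow-up, optional mutation/CNV calls, GMT
gene sets):

1. clean the cohort (follow-up filters, duplicate-gene collapsing);
2. tabulate the regulator landscape (mutation %, CNV gain/loss %,
   co-expression, two-group tests);
3. discover subtypes by **consensus k-medoids clustering** (Monti
   resampling over 1 − Pearson distance, CDF/delta-area/PAC diagnostics);
4. call subtype **DEGs** with an empirical-Bayes moderated t
   (p < 0.05 and |log2FC| > 1);
5. screen DEGs by univariate **Cox** regression (Breslow partial
   likelihood), z-score the survivors, run PCA, and score each sample

   DMS = σ₁·PC1 + σ₂·PC2,

   the sum of the sample's first two principal-component scores, with
   signs σ oriented so that high DMS tracks protective (HR < 1) genes;
6. dichotomize DMS at the **maximally selected log-rank cutpoint** and
   compare Kaplan–Meier curves;
7. run gene-set enrichment (weighted-KS GSEA, hypergeometric ORA,
   per-sample signature scores).

A synthetic-cohort generator (`methscore.syndata`) plants known cluster
structure, a dominant prognostic gene program and censored survival, so
the whole chain is testable offline with full ground truth — no downloads
required.

## Worked example

Everything below is computed on a simulated 200-sample cohort (3 planted
subtypes, a planted prognostic program, 30% censoring):

```python
import methscore as ms

cohort = ms.simulate_cohort(ms.SimulationConfig(n_samples=200, seed=7))

res = ms.consensus_cluster(cohort.expression, list(ms.DEFAULT_PANEL),
                           k_range=(2, 3, 4, 5), n_resamples=100, seed=7)
# recommended k: 3 | PAC: {2: 0.706, 3: 0.0, 4: 0.188, 5: 0.247}

clusters = res.assignments[res.chosen_k]
sub = clusters[clusters.isin([2, 3])]
table = ms.moderated_t(cohort.expression[list(sub.index)], sub, 2, 3)
call = ms.call_degs(table)
# DEGs: {'up': 60, 'down': 48, 'total': 108}

screen = ms.cox_screen(cohort.expression, cohort.clinical, call.genes)
model, scores = ms.fit_dms(cohort.expression, screen)
# screened genes: 100 | explained variance: [0.63, 0.089]

cut = ms.find_cutpoint(scores["dms"].to_numpy(),
                       cohort.clinical["os_time"].to_numpy(),
                       cohort.clinical["os_status"].to_numpy())
# cutpoint: -3.674 | log-rank chi2 = 101.8, p = 6.20e-24
# median survival (days): {'Low_DMS': 146.6, 'High_DMS': 1072.6}
# corr(DMS, planted latent score) = 0.954
```

Reading the numbers: PAC (proportion of ambiguous clustering) is
essentially 0 at k = 3, so the three planted subtypes are recovered
cleanly; 108 genes pass the DEG rule between two subtypes; 100 survive the
Cox screen and PC1 of their z-scores carries 63% of the variance; splitting
the cohort at the optimal DMS cutpoint separates median survival by roughly
a factor of seven, and the score correlates 0.95 with the planted latent
prognostic score.

The same chain runs from the shell:

```bash
methscore run-all --simulate --seed 7 --out results_run --reps 100
# pipeline complete: 8 stages -> results_run
# High vs Low DMS log-rank p = 4.22e-14; medians = {'Low_DMS': 126.07..., 'High_DMS': 733.63...}
```

which writes every intermediate table (cluster assignments, consensus
matrices, DEG table, Cox screen, DMS model and scores, cutpoint scan, KM
curves, GSEA/ORA, group crosstab) plus `manifest.json` recording seeds,
parameters and row counts. Subcommands (`simulate`, `preprocess`,
`landscape`, `cluster`, `deg`, `score`, `survival`, `enrich`) expose each
stage separately; `methscore <cmd> --help` lists the options. Real cohorts
are supplied with `--expression`/`--clinical` (TSV) instead of
`--simulate`.

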