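"""Descriptive genomics of the 5mC regulator panel.

The panel collects the genes that write (DNMTs), erase (TETs) and read
(MBDs, ZBTBs, UHRFs, glycosylases) 5-methylcytosine.  This module tabulates
their mutation and copy-number alteration frequencies across a cohort, runs
tumor-vs-normal style two-group expression tests, builds co-expression /
immune-correlate correlation matrices, and cross-tabulates sample groupings.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Default 5mC regulator panel: role of each of the 20 genes.
DEFAULT_PANEL: dict[str, str] = {
    "DNMT1": "writer", "DNMT3A": "writer", "DNMT3B": "writer",
    "TET1": "eraser", "TET2": "eraser", "TET3": "eraser",
    "ZBTB33": "reader", "ZBTB38": "reader", "ZBTB4": "reader",
    "MBD1": "reader", "MBD2": "reader", "MBD3": "reader", "MBD4": "reader",
    "MECP2": "reader", "UNG": "reader", "TDG": "reader",
    "NTHL1": "reader", "SMUG1": "reader", "UHRF1": "reader", "UHRF2": "reader",
}


def _panel_genes(panel: Mapping[str, str] | Sequence[str] | None) -> list[str]:
    if panel is None:
        return list(DEFAULT_PANEL)
    if isinstance(panel, Mapping):
        return list(panel)
    return list(panel)


# ---------------------------------------------------------------------------
# mutation / CNV frequencies
# ---------------------------------------------------------------------------

def mutation_frequency(
    mutations: pd.DataFrame,
    sample_universe: Sequence[str],
    panel: Mapping[str, str] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Percent of samples carrying >= 1 mutation per panel gene.

    The denominator is ``sample_universe`` — every profiled sample, not only
    mutated ones — and a sample counts at most once per gene regardless of
    how many variants it carries there.
    """
    universe = list(dict.fromkeys(str(s) for s in sample_universe))
    if not universe:
        raise ValueError("sample_universe is empty")
    genes = _panel_genes(panel)
    in_universe = mutations[mutations["sample_id"].isin(universe)]
    per_gene = (
        in_universe.drop_duplicates(subset=["sample_id", "gene"])
        .groupby("gene")["sample_id"].size()
    )
    n_mutated = pd.Series([int(per_gene.get(g, 0)) for g in genes], index=genes)
    out = pd.DataFrame({
        "gene": genes,
        "n_mutated": n_mutated.to_numpy(),
        "n_samples": len(universe),
        "mutated_pct": 100.0 * n_mutated.to_numpy() / len(universe),
    }).set_index("gene")
    return out


def cnv_frequency(
    cnv: pd.DataFrame,
    panel: Mapping[str, str] | Sequence[str] | None = None,
    gain_threshold: int = 1,
    loss_threshold: int = -1,
) -> pd.DataFrame:
    """Percent of samples with CNV gain (call >= gain_threshold) and loss
    (call <= loss_threshold) per panel gene present in the CNV table."""
    genes = [g for g in _panel_genes(panel) if g in cnv.index]
    if not genes:
        raise ValueError("no panel genes present in the CNV table")
    sub = cnv.loc[genes]
    n = sub.shape[1]
    gain = (sub >= gain_threshold).sum(axis=1)
    loss = (sub <= loss_threshold).sum(axis=1)
    return pd.DataFrame({
        "n_samples": n,
        "gain_pct": 100.0 * gain / n,
        "loss_pct": 100.0 * loss / n,
    }, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# two-group expression tests
# ---------------------------------------------------------------------------

def two_group_expression_test(
    expression: pd.DataFrame,
    group_labels: pd.Series | Mapping[str, object],
    method: str = "wilcoxon",
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-gene two-group test (Wilcoxon rank-sum or Welch t).

    The Wilcoxon p is exact when the smaller group has <= ``exact_max_n``
    samples and the gene has no ties, and otherwise uses the normal
    approximation with tie and continuity corrections.  ``direction`` is the
    sign of mean(group A) - mean(group B) where A is the first group in
    sorted label order.  Benjamini-Hochberg adjusted p-values are reported
    alongside.
    """
    labels = pd.Series(group_labels)
    labels = labels.loc[[s for s in expression.columns if s in labels.index]]
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    a_ids = labels.index[labels == groups[0]]
    b_ids = labels.index[labels == groups[1]]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 samples")

    A = expression[a_ids].to_numpy(float)
    B = expression[b_ids].to_numpy(float)
    n_genes = expression.shape[0]
    stat = np.empty(n_genes)
    pval = np.empty(n_genes)
    if method == "wilcoxon":
        small = min(A.shape[1], B.shape[1])
        for i in range(n_genes):
            pooled = np.concatenate([A[i], B[i]])
            has_ties = len(np.unique(pooled)) < len(pooled)
            mode = "exact" if (small <= exact_max_n and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(A[i], B[i], alternative="two-sided", method=mode)
            stat[i], pval[i] = res.statistic, res.pvalue
    elif method == "t":
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        stat, pval = np.asarray(res.statistic), np.asarray(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    diff = A.mean(axis=1) - B.mean(axis=1)
    out = pd.DataFrame({
        "statistic": stat,
        "p": pval,
        "p_adj": multipletests(pval, method="fdr_bh")[1],
        "mean_diff": diff,
        "direction": np.where(diff >= 0, f"up_in_{groups[0]}", f"up_in_{groups[1]}"),
    }, index=expression.index.copy())
    return out


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

def correlation_matrix(
    expression: pd.DataFrame,
    features: Sequence[str] | None = None,
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric feature-feature correlation matrix with p-values.

    ``features`` selects rows of the expression matrix (default: all).
    Returns ``(r, p)`` with unit diagonal on ``r`` and zero diagonal on ``p``.
    """
    if features is not None:
        missing = [g for g in features if g not in expression.index]
        if missing:
            raise KeyError(f"features absent from expression matrix: {missing}")
        expression = expression.loc[list(features)]
    X = expression.to_numpy(float)  # features x samples
    n = X.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation p-values")

    if method == "spearman":
        r, p = stats.spearmanr(X, axis=1)
        r, p = np.atleast_2d(r), np.atleast_2d(p)
    elif method == "pearson":
        r = np.corrcoef(X)
        rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = rr * np.sqrt((n - 2) / (1 - rr**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")

    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    idx = expression.index.copy()
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


# ---------------------------------------------------------------------------
# group cross-tabulation
# ---------------------------------------------------------------------------

def group_crosstab(*label_sets: pd.Series, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Contingency counts over one or more sample groupings.

    With one grouping this is its value counts; with several, the count of
    samples per combination (a tabular stand-in for an alluvial diagram).
    Marginals sum to the number of common samples.
    """
    if not label_sets:
        raise ValueError("need at least one grouping")
    series = [pd.Series(ls) for ls in label_sets]
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    common = sorted(common)
    if not common:
        raise ValueError("groupings share no samples")
    series = [s.loc[common] for s in series]
    if names is None:
        names = [s.name or f"grouping_{i+1}" for i, s in enumerate(series)]
    df = pd.DataFrame({name: s.to_numpy() for name, s in zip(names, series)},
                      index=common)
    out = df.value_counts(sort=False).rename("n_samples").reset_index()
    return out.sort_values(list(names), kind="stable").reset_index(drop=True)
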