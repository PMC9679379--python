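"""Gene-set analysis: weighted-KS GSEA with a permutation null,
hypergeometric over-representation, per-sample signature scoring, and the
k-group location test used for factor-panel comparisons.

GSEA follows the weighted Kolmogorov-Smirnov running sum: walking down the
list ranked by a per-gene statistic, set members advance the sum by
|stat|^p normalized over the in-set total and non-members retreat by
1/(N - K); the enrichment score is the extremum by absolute value.
Significance uses a gene-set permutation null (random same-size sets),
with NES = ES / mean(|null ES| of the same sign) and a same-sign empirical
p-value; phenotype permutation is available when a two-group design is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .preprocess import zscore_genes


def _as_set_dict(gene_sets) -> dict[str, list[str]]:
    if isinstance(gene_sets, GeneSetCollection):
        return gene_sets.as_dict()
    return {name: list(genes) for name, genes in dict(gene_sets).items()}


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def gsea_es(
    ranked_genes: Sequence[str],
    ranking_stat: Sequence[float],
    gene_set: Sequence[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Enrichment score of one gene set on a ranked list.

    ``ranked_genes`` must be sorted by ``ranking_stat`` descending.  Returns
    (ES, running sum, leading-edge genes).
    """
    genes = list(ranked_genes)
    stat = np.asarray(ranking_stat, dtype=float)
    if len(genes) != len(stat):
        raise ValueError("ranked_genes and ranking_stat length mismatch")
    if np.any(np.diff(stat) > 1e-12):
        raise ValueError("ranking_stat must be sorted descending")
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    N, K = len(genes), int(hit.sum())
    if K == 0:
        raise ValueError("gene set shares no genes with the ranked list")

    w = np.abs(stat) ** weight_p
    hit_total = w[hit].sum()
    steps = np.where(hit,
                     w / hit_total if hit_total > 0 else 1.0 / K,
                     -1.0 / (N - K) if N > K else 0.0)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hit[peak:]) if h]
    return es, running, leading


@dataclass
class GseaResult:
    table: pd.DataFrame                 # per set: es, nes, p, q, size, leading edge
    n_permutations: int
    perm_type: str

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def gsea_run(
    ranked_genes: Sequence[str],
    stats_values: Sequence[float],
    gene_sets,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    perm_type: str = "gene_set",
    seed: int | None = 0,
    expression: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
) -> GseaResult:
    """GSEA over a collection of gene sets with a permutation null.

    gene_set permutation (default) draws random same-size sets from the
    ranked list; phenotype permutation shuffles the two-group labels and
    re-ranks by group mean difference (requires ``expression``+``labels``).
    """
    sets = _as_set_dict(gene_sets)
    order = np.argsort(-np.asarray(stats_values, dtype=float), kind="stable")
    genes = [list(ranked_genes)[i] for i in order]
    stat = np.asarray(stats_values, dtype=float)[order]
    rng = np.random.default_rng(seed)
    N = len(genes)

    if perm_type == "phenotype":
        if expression is None or labels is None:
            raise ValueError("phenotype permutation needs expression and labels")
        null_by_set = _phenotype_null(expression, labels, sets, n_perm,
                                      weight_p, rng)
    elif perm_type != "gene_set":
        raise ValueError(f"unknown perm_type {perm_type!r}")

    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in set(genes)]
        if not present:
            rows.append((name, 0, np.nan, np.nan, np.nan, ""))
            continue
        es, _, leading = gsea_es(genes, stat, present, weight_p)
        K = len(present)
        if perm_type == "gene_set":
            null = np.empty(n_perm)
            for b in range(n_perm):
                idx = rng.choice(N, size=K, replace=False)
                rand_set = [genes[i] for i in idx]
                null[b], _, _ = gsea_es(genes, stat, rand_set, weight_p)
        else:
            null = null_by_set[name]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size:
            p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
            denom = float(np.abs(same_sign).mean())
            nes = es / denom if denom > 0 else np.nan
        else:
            p, nes = 1.0 / (1 + n_perm), np.nan
        rows.append((name, K, es, nes, p, ",".join(leading)))

    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p",
                                        "leading_edge"]).set_index("set")
    valid = table["p"].notna()
    q = np.full(len(table), np.nan)
    if valid.any():
        q[valid.to_numpy()] = multipletests(table.loc[valid, "p"],
                                            method="fdr_bh")[1]
    table.insert(4, "q", q)
    return GseaResult(table=table, n_permutations=n_perm, perm_type=perm_type)


def _phenotype_null(expression, labels, sets, n_perm, weight_p, rng):
    labels = pd.Series(labels)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ValueError("phenotype permutation needs exactly 2 groups")
    X = expression.to_numpy(float)
    genes_all = list(expression.index)
    lab = labels.loc[expression.columns].to_numpy()
    null_by_set = {name: np.empty(n_perm) for name in sets}
    for b in range(n_perm):
        perm = rng.permutation(lab)
        diff = X[:, perm == uniq[0]].mean(axis=1) - X[:, perm == uniq[1]].mean(axis=1)
        order = np.argsort(-diff, kind="stable")
        genes = [genes_all[i] for i in order]
        for name, members in sets.items():
            present = [g for g in members if g in set(genes)]
            if present:
                null_by_set[name][b], _, _ = gsea_es(genes, diff[order], present,
                                                     weight_p)
            else:
                null_by_set[name][b] = np.nan
    return null_by_set


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def ora_hypergeometric(
    gene_list: Sequence[str],
    gene_sets,
    universe: Sequence[str],
    min_size: int = 1,
    max_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    p = P(X >= k) with X ~ Hypergeom(N = |universe|, K = |set ∩ universe|,
    n = |list ∩ universe|); BH-adjusted q across tested sets.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    N = len(uni)
    hits = [g for g in dict.fromkeys(gene_list) if g in uni_set]
    n = len(hits)
    hit_set = set(hits)
    rows = []
    for name, members in _as_set_dict(gene_sets).items():
        K = len(set(members) & uni_set)
        if K < min_size or (max_size is not None and K > max_size):
            continue
        k = len(set(members) & hit_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    if not rows:
        raise ValueError("no gene set passes the size filter")
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "list_size", "universe_size", "p"]
                       ).set_index("set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# per-sample signature scores
# ---------------------------------------------------------------------------

def signature_score(
    expression: pd.DataFrame,
    gene_sets,
    method: str = "mean_z",
    ssgsea_exponent: float = 0.25,
) -> pd.DataFrame:
    """Per-sample activity of each signature (samples x sets).

    ``mean_z`` averages the z-scored expression of member genes present in
    the matrix; ``ssgsea`` computes a single-sample rank-based enrichment:
    the normalized integral difference between the weighted in-set ECDF
    (rank weight ^ exponent) and the out-of-set ECDF down the sample's own
    expression ranking.
    """
    sets = _as_set_dict(gene_sets)
    cols = {}
    if method == "mean_z":
        Z = zscore_genes(expression)
        for name, members in sets.items():
            present = [g for g in members if g in Z.index]
            if not present:
                raise KeyError(f"set {name!r} has no genes in the matrix")
            cols[name] = Z.loc[present].mean(axis=0)
    elif method == "ssgsea":
        X = expression.to_numpy(float)
        genes = list(expression.index)
        N = len(genes)
        order = np.argsort(-X, axis=0, kind="stable")
        rank_weight = (N - np.arange(N)).astype(float) ** ssgsea_exponent
        for name, members in sets.items():
            members = set(members) & set(genes)
            if not members:
                raise KeyError(f"set {name!r} has no genes in the matrix")
            member_mask = np.array([g in members for g in genes])
            scores = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                hit = member_mask[order[:, j]]
                w = np.where(hit, rank_weight, 0.0)
                in_cdf = np.cumsum(w) / w.sum()
                out_cdf = np.cumsum(~hit) / (N - hit.sum())
                scores[j] = float((in_cdf - out_cdf).sum()) / N
            cols[name] = pd.Series(scores, index=expression.columns)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(cols, index=expression.columns)


# ---------------------------------------------------------------------------
# k-group location test
# ---------------------------------------------------------------------------

def kgroup_test(
    expression: pd.DataFrame,
    group_labels: pd.Series | Mapping[str, object],
    method: str = "kruskal",
) -> pd.DataFrame:
    """Per-gene k-group test: Kruskal-Wallis (default) or one-way ANOVA,
    with BH-adjusted p alongside."""
    labels = pd.Series(group_labels)
    labels = labels.loc[[s for s in expression.columns if s in labels.index]].dropna()
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    blocks = [expression[list(labels.index[labels == g])].to_numpy(float)
              for g in groups]
    n_genes = expression.shape[0]
    stat = np.empty(n_genes)
    pval = np.empty(n_genes)
    test = stats.kruskal if method == "kruskal" else stats.f_oneway
    if method not in ("kruskal", "anova"):
        raise ValueError(f"unknown method {method!r}")
    for i in range(n_genes):
        try:
            res = test(*[b[i] for b in blocks])
            stat[i], pval[i] = res.statistic, res.pvalue
        except ValueError:          # all values identical
            stat[i], pval[i] = 0.0, 1.0
    return pd.DataFrame({
        "statistic": stat,
        "p": pval,
        "p_adj": multipletests(pval, method="fdr_bh")[1],
    }, index=expression.index.copy())
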