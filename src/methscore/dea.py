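"""Two-group differential expression with empirical-Bayes moderated t.

Per gene, an ordinary two-group linear model (pooled residual variance
s_g^2 on d_g = nA + nB - 2 degrees of freedom) is shrunk towards a global
prior variance: the prior (d0, s0^2) is estimated by moment matching on
log s_g^2 using digamma/trigamma identities of the scaled-F distribution of
sample variances, the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t = log2FC / (s~_g * sqrt(1/nA + 1/nB)) is referred to a
t distribution on d0 + d_g degrees of freedom.  With d0 forced to 0 the
statistic reduces exactly to the ordinary pooled-variance t.

DEG calling uses the conventional rule: raw p below ``p_cut`` (default
0.05) and |log2 fold change| strictly greater than ``lfc_cut`` (default 1),
with BH-adjusted p reported alongside and available as the threshold via
``use_adjusted``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the inverse-chi-square variance prior.

    Moment matching on e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2):
    mean(e) = log s0^2 + digamma(d0/2) - log(d0/2) and
    var(e) = trigamma(d_g/2) + trigamma(d0/2); the second is inverted for
    d0.  When the observed spread is no larger than the sampling spread the
    prior is degenerate (d0 = inf, every variance shrunk to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s02


def moderated_t(
    expression: pd.DataFrame,
    labels: pd.Series | Mapping[str, object],
    group_a: object | None = None,
    group_b: object | None = None,
    d0: float | None = None,
) -> pd.DataFrame:
    """Moderated-t table for a two-group contrast.

    ``log2fc`` is mean(group A) - mean(group B); by default A and B are the
    two labels in sorted order, overridable with ``group_a``/``group_b``
    (e.g. the paper-style contrast of two named subtypes).  ``d0=None``
    estimates the prior from the data; ``d0=0`` disables shrinkage.

    Zero-variance genes whose group means are also equal get t = 0, p = 1
    and a ``degenerate`` flag.
    """
    labels = pd.Series(labels)
    labels = labels.loc[[s for s in expression.columns if s in labels.index]].dropna()
    uniq = sorted(labels.unique())
    if group_a is None and group_b is None:
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 groups, got {uniq}")
        group_a, group_b = uniq
    elif group_a is None or group_b is None:
        raise ValueError("give both group_a and group_b or neither")
    a_ids = labels.index[labels == group_a]
    b_ids = labels.index[labels == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 samples")

    A = expression[list(a_ids)].to_numpy(float)
    B = expression[list(b_ids)].to_numpy(float)
    nA, nB = A.shape[1], B.shape[1]
    dg = nA + nB - 2
    lfc = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / dg

    if d0 is None:
        d0_hat, s02 = fit_variance_prior(s2, dg)
    elif d0 == 0:
        d0_hat, s02 = 0.0, 0.0
    else:
        d0_hat = float(d0)
        _, s02 = fit_variance_prior(s2, dg)

    if np.isinf(d0_hat):
        post_s2 = np.full_like(s2, s02)
        df_total = np.inf
    else:
        post_s2 = (d0_hat * s02 + dg * s2) / (d0_hat + dg)
        df_total = d0_hat + dg

    se = np.sqrt(post_s2 * (1.0 / nA + 1.0 / nB))
    degenerate = se == 0
    t = np.zeros_like(lfc)
    np.divide(lfc, se, out=t, where=~degenerate)
    t[degenerate & (lfc == 0)] = 0.0
    t[degenerate & (lfc != 0)] = np.sign(lfc[degenerate & (lfc != 0)]) * np.inf
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p[degenerate & (lfc == 0)] = 1.0

    out = pd.DataFrame({
        "log2fc": lfc,
        "t": t,
        "p": p,
        "p_adj": multipletests(p, method="fdr_bh")[1],
        "direction": np.where(lfc >= 0, f"up_in_{group_a}", f"up_in_{group_b}"),
        "degenerate": degenerate,
    }, index=expression.index.copy())
    out.attrs["d0"] = d0_hat
    out.attrs["s0_sq"] = s02
    out.attrs["groups"] = (group_a, group_b)
    out["passes_threshold"] = (out["p"] < 0.05) & (out["log2fc"].abs() > 1.0)
    return out


@dataclass
class DegCall:
    up: list[str]
    down: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    @property
    def counts(self) -> dict[str, int]:
        return {"up": len(self.up), "down": len(self.down),
                "total": len(self.up) + len(self.down)}


def call_degs(table: pd.DataFrame, p_cut: float = 0.05, lfc_cut: float = 1.0,
              use_adjusted: bool = False) -> DegCall:
    """Partition genes passing (p < p_cut) and (|log2FC| > lfc_cut, strict)
    into up- (log2FC > 0, higher in group A) and down-regulated lists."""
    p = table["p_adj"] if use_adjusted else table["p"]
    passing = (p < p_cut) & (table["log2fc"].abs() > lfc_cut)
    up = list(table.index[passing & (table["log2fc"] > 0)])
    down = list(table.index[passing & (table["log2fc"] < 0)])
    return DegCall(up=up, down=down)


def pairwise_union_degs(
    expression: pd.DataFrame,
    labels: pd.Series,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
    use_adjusted: bool = False,
) -> list[str]:
    """Union of DEG calls over every pair of groups (any-pair mode)."""
    labels = pd.Series(labels)
    uniq = sorted(labels.dropna().unique())
    genes: dict[str, None] = {}
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            sub = labels[labels.isin([a, b])]
            table = moderated_t(expression[list(sub.index)], sub, a, b)
            for g in call_degs(table, p_cut, lfc_cut, use_adjusted).genes:
                genes.setdefault(g)
    return list(genes)
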