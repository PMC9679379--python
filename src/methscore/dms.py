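"""The DNA methylation score (DMS): univariate Cox screening of candidate
genes, per-gene standardization, PCA, and the per-sample score

    DMS = sigma1 * PC1 + sigma2 * PC2,

the sum of each sample's scores on the first two principal components of
the screened-gene z-score matrix.  PCA leaves the sign of each component
arbitrary, so the orientation signs sigma_m are fixed by an anchor: each
component is flipped, if needed, so it correlates non-negatively with the
per-sample mean z-expression of the protective screened genes (univariate
hazard ratio < 1).  With that convention a high DMS tracks protective
expression, i.e. the high-DMS group is the longer-surviving one.

Screening fits, for every candidate gene separately, a univariate Cox
proportional-hazards model by Newton-Raphson maximization of the Breslow
partial likelihood, and keeps genes with Wald p below ``alpha``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import zscore_genes

logger = logging.getLogger("methscore")


# ---------------------------------------------------------------------------
# univariate Cox (Breslow ties)
# ---------------------------------------------------------------------------

def breslow_partial_loglik(beta: float, x: np.ndarray, time: np.ndarray,
                           event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a single covariate at ``beta``."""
    order = np.argsort(-time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    eta = beta * x
    cum = np.logaddexp.accumulate(eta)          # log sum over risk set (desc time)
    # risk set of a death at t includes all with time >= t: with descending
    # order and ties, the full tie block must be inside the cumulative sum
    ll = 0.0
    i = 0
    n = len(x)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        block = slice(i, j)
        deaths = event[block] == 1
        if deaths.any():
            ll += float(eta[block][deaths].sum()) - deaths.sum() * float(cum[j - 1])
        i = j
    return ll


def _cox_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 50, tol: float = 1e-10
                ) -> tuple[float, float, bool]:
    """Newton-Raphson for the univariate Breslow partial likelihood.

    Returns (beta, se, converged).  Non-convergence or a diverging
    coefficient (|beta| > 50) is reported, not raised.
    """
    order = np.argsort(-time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    n = len(x)
    # tie blocks of equal time, descending
    block_end = np.nonzero(np.diff(time) != 0)[0].tolist() + [n - 1]

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        U = H = 0.0
        i = 0
        for end in block_end:
            block = slice(i, end + 1)
            d = event[block] == 1
            nd = int(d.sum())
            if nd:
                m1 = s1[end] / s0[end]
                U += float(x[block][d].sum()) - nd * m1
                H += nd * (s2[end] / s0[end] - m1 * m1)
            i = end + 1
        if H <= 0:
            return beta, np.inf, False
        step = U / H
        beta_new = beta + step
        if abs(beta_new) > 50:
            return beta_new, np.inf, False
        if abs(step) < tol:
            return beta_new, 1.0 / np.sqrt(H), True
        beta = beta_new
    return beta, 1.0 / np.sqrt(H) if H > 0 else np.inf, False


def cox_screen(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    candidate_genes: Sequence[str],
    alpha: float = 0.05,
    min_events: int = 10,
) -> pd.DataFrame:
    """Univariate Cox fit per candidate gene; keep genes with Wald p < alpha.

    Returns the full per-gene table (coef, HR, se, z, p, kept, converged).
    Constant-expression genes and non-converging fits are flagged, excluded
    from the kept set and logged, never silently dropped.
    """
    missing = [g for g in candidate_genes if g not in expression.index]
    if missing:
        raise KeyError(f"candidate genes absent from expression: {missing[:5]}...")
    samples = [s for s in expression.columns if s in clinical.index]
    if len(samples) < len(expression.columns):
        logger.info("cox_screen: %d expression samples lack clinical data",
                    len(expression.columns) - len(samples))
    time = clinical.loc[samples, "os_time"].to_numpy(float)
    event = clinical.loc[samples, "os_status"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events in the cohort; Cox screening impossible")
    if event.sum() < min_events:
        warnings.warn(f"only {int(event.sum())} events (< {min_events}); "
                      "screening will be unstable", stacklevel=2)

    rows = []
    for gene in candidate_genes:
        x = expression.loc[gene, samples].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        beta, se, converged = _cox_newton(x, time, event)
        if not converged or not np.isfinite(se):
            rows.append((gene, beta, np.exp(beta), se, np.nan, np.nan, False, converged))
            continue
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append((gene, beta, np.exp(beta), se, z, p, p < alpha, True))
    out = pd.DataFrame(rows, columns=["gene", "coef", "hr", "se", "z", "p",
                                      "kept", "converged"]).set_index("gene")
    n_bad = int((~out["converged"].astype(bool)).sum())
    if n_bad:
        logger.warning("cox_screen: %d genes flagged (constant or non-converged)",
                       n_bad)
    return out


# ---------------------------------------------------------------------------
# DMS model
# ---------------------------------------------------------------------------

@dataclass
class DmsModel:
    """Frozen DMS scorer: screened genes, their standardization constants,
    the first two PC loading vectors and the orientation signs."""

    genes: list[str]
    means: pd.Series
    sds: pd.Series
    loadings: pd.DataFrame          # genes x [pc1, pc2], unit-norm columns
    signs: tuple[int, int]
    explained_variance_ratio: tuple[float, float]
    protective_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.loadings.copy()
        out.insert(0, "mean", self.means)
        out.insert(1, "sd", self.sds)
        out["protective"] = [g in set(self.protective_genes) for g in out.index]
        out.attrs["signs"] = self.signs
        return out


def _pc_scores(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the samples x genes z-matrix -> (scores, loadings, evr)."""
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((S**2).sum())
    n_pc = min(2, len(S))
    scores = U[:, :n_pc] * S[:n_pc]
    loadings = Vt[:n_pc].T
    evr = S[:n_pc] ** 2 / total if total > 0 else np.zeros(n_pc)
    if n_pc < 2:
        scores = np.column_stack([scores, np.zeros(Z.shape[0])])
        loadings = np.column_stack([loadings, np.zeros(Z.shape[1])])
        evr = np.append(evr, 0.0)
    return scores, loadings, evr


def fit_dms(
    expression: pd.DataFrame,
    screened_genes: Sequence[str] | pd.DataFrame,
) -> tuple[DmsModel, pd.DataFrame]:
    """Fit the DMS model on a training cohort.

    ``screened_genes`` is either the :func:`cox_screen` table (its kept
    genes are used, and genes with HR < 1 anchor the orientation) or a plain
    gene list (every gene anchors).  Returns the model and a per-sample
    result frame with ``pc1``, ``pc2`` and ``dms`` columns.
    """
    if isinstance(screened_genes, pd.DataFrame):
        table = screened_genes
        genes = list(table.index[table["kept"].astype(bool)])
        protective = list(table.index[table["kept"].astype(bool)
                                      & (table["hr"] < 1)])
        if not protective:
            protective = genes
    else:
        genes = list(screened_genes)
        protective = genes
    if not genes:
        raise ValueError("no screened genes to build the DMS from")
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise KeyError(f"screened genes absent from expression: {missing[:5]}...")
    if len(genes) < 2:
        warnings.warn("fewer than 2 screened genes; single-component DMS",
                      stacklevel=2)

    sub = expression.loc[genes]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=0)
    if (sds == 0).any():
        dropped = list(sub.index[sds == 0])
        warnings.warn(f"dropping {len(dropped)} constant screened genes",
                      stacklevel=2)
        genes = [g for g in genes if g not in set(dropped)]
        protective = [g for g in protective if g not in set(dropped)]
        sub, means, sds = sub.loc[genes], means.loc[genes], sds.loc[genes]

    Z = ((sub.sub(means, axis=0)).div(sds, axis=0)).to_numpy().T  # samples x genes
    scores, loadings, evr = _pc_scores(Z)

    anchor = Z[:, [genes.index(g) for g in protective]].mean(axis=1)
    signs = []
    for m in range(2):
        c = float(np.dot(scores[:, m] - scores[:, m].mean(),
                         anchor - anchor.mean()))
        signs.append(-1 if c < 0 else 1)
    signs = (signs[0], signs[1])

    model = DmsModel(
        genes=genes, means=means, sds=sds,
        loadings=pd.DataFrame(loadings, index=genes, columns=["pc1", "pc2"]),
        signs=signs,
        explained_variance_ratio=(float(evr[0]), float(evr[1])),
        protective_genes=protective,
    )
    result = pd.DataFrame({
        "pc1": signs[0] * scores[:, 0],
        "pc2": signs[1] * scores[:, 1],
    }, index=pd.Index(expression.columns, name="sample_id"))
    result["dms"] = result["pc1"] + result["pc2"]
    return model, result


def apply_dms(
    model: DmsModel,
    expression_new: pd.DataFrame,
    use_train_scale: bool = False,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Score a new cohort with a fitted DMS model.

    By default genes are standardized with the NEW cohort's own means/SDs
    (robust to cross-platform scale differences); ``use_train_scale``
    switches to the stored training constants.  Screened genes missing from
    the new cohort are imputed at z = 0 (count logged); at least
    ``min_coverage`` of the screened genes must be present.
    """
    present = [g for g in model.genes if g in expression_new.index]
    coverage = len(present) / len(model.genes)
    if coverage < min_coverage:
        raise ValueError(
            f"new cohort covers only {coverage:.0%} of screened genes "
            f"(minimum {min_coverage:.0%})"
        )
    n_missing = len(model.genes) - len(present)
    if n_missing:
        logger.info("apply_dms: %d screened genes missing, imputed at z=0",
                    n_missing)
    sub = expression_new.loc[present]
    if use_train_scale:
        mu, sd = model.means.loc[present], model.sds.loc[present]
    else:
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
        sd = sd.mask(sd == 0, 1.0)
    Zp = ((sub.sub(mu, axis=0)).div(sd, axis=0)).to_numpy()
    Z = np.zeros((len(model.genes), expression_new.shape[1]))
    pos = {g: i for i, g in enumerate(model.genes)}
    for g, row in zip(present, Zp):
        Z[pos[g]] = row
    scores = Z.T @ model.loadings.to_numpy()
    result = pd.DataFrame({
        "pc1": model.signs[0] * scores[:, 0],
        "pc2": model.signs[1] * scores[:, 1],
    }, index=pd.Index(expression_new.columns, name="sample_id"))
    result["dms"] = result["pc1"] + result["pc2"]
    result.attrs["n_missing_genes"] = n_missing
    return result
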