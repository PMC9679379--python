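"""Resampling-based consensus clustering with PAM (k-medoids) partitioning.

The procedure follows the Monti consensus-clustering scheme: for each of
``R`` resamples, draw ``ceil(p_item * n)`` samples without replacement,
partition them with PAM on the induced distance sub-matrix, and accumulate
the fraction of resamples in which each co-sampled pair lands in the same
cluster.  The per-k consensus matrix feeds

* the final subtype call — average-linkage hierarchical clustering of
  ``1 - consensus`` cut at k (clusters then relabeled 1..k by decreasing
  size);
* the empirical CDF of off-diagonal consensus values, its delta-area elbow
  across k, and PAC = CDF(0.9) - CDF(0.1) for choosing k.

PAM here is the classic build + swap algorithm: a greedy build minimizing
total distance-to-nearest-medoid, then first-improvement swaps scanned in
fixed (medoid index, candidate index) order, which makes the result
deterministic given the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import zscore_genes

_TOL = 1e-9


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def correlation_distance(expression: pd.DataFrame,
                         features: Sequence[str] | None = None) -> pd.DataFrame:
    """1 - Pearson correlation between samples over z-scored feature genes."""
    if features is not None:
        missing = [g for g in features if g not in expression.index]
        if missing:
            raise KeyError(f"features absent from expression matrix: {missing}")
        expression = expression.loc[list(features)]
    Z = zscore_genes(expression).to_numpy()
    r = np.corrcoef(Z.T)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expression.columns, columns=expression.columns)


def euclidean_distance(expression: pd.DataFrame,
                       features: Sequence[str] | None = None) -> pd.DataFrame:
    if features is not None:
        expression = expression.loc[list(features)]
    X = zscore_genes(expression).to_numpy().T  # samples x genes
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expression.columns, columns=expression.columns)


DISTANCES = {"correlation": correlation_distance, "euclidean": euclidean_distance}


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(D.sum(axis=1).argmin())]
    near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate h: total reduction in nearest distances
        gain = np.maximum(near[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        h = int(gain.argmax())
        medoids.append(h)
        near = np.minimum(near, D[:, h])
    return sorted(medoids)


def _pam_swap(D: np.ndarray, medoids: list[int]) -> list[int]:
    n = D.shape[0]
    while True:
        med = np.asarray(sorted(medoids))
        Dm = D[:, med]                      # n x k
        order = np.argsort(Dm, axis=1, kind="stable")
        near_idx = order[:, 0]              # position within med
        near = Dm[np.arange(n), near_idx]
        if len(med) > 1:
            second = Dm[np.arange(n), order[:, 1]]
        else:
            second = np.full(n, np.inf)
        cands = np.setdiff1d(np.arange(n), med)
        improved = False
        for mi, m in enumerate(med):        # fixed medoid-index order
            owned = near_idx == mi
            C = D[np.ix_(cands, np.arange(n))]   # candidates x points
            new_owned = np.minimum(C[:, owned], second[owned]) - near[owned]
            new_other = np.minimum(C[:, ~owned], near[~owned]) - near[~owned]
            delta = new_owned.sum(axis=1) + new_other.sum(axis=1)
            good = np.nonzero(delta < -_TOL)[0]
            if good.size:                    # first improvement: lowest cand index
                h = int(cands[good[0]])
                medoids = sorted(set(med.tolist()) - {int(m)} | {h})
                improved = True
                break
        if not improved:
            return sorted(int(m) for m in med)


def _exact_medoids(D: np.ndarray, k: int) -> list[int]:
    """Exhaustive k-medoid search; ties go to the lexicographically smallest
    medoid set.  Only used when C(n, k) is small."""
    from itertools import combinations

    best_cost, best = np.inf, None
    for subset in combinations(range(D.shape[0]), k):
        cost = float(np.min(D[:, subset], axis=1).sum())
        if cost < best_cost - _TOL:
            best_cost, best = cost, subset
    return list(best)


#: instances with at most this many medoid subsets are solved exactly
EXACT_SUBSET_LIMIT = 1000


def kmedoids(distance_matrix: np.ndarray | pd.DataFrame, k: int,
             init_seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """k-medoids partition of a square symmetric distance matrix.

    Returns ``(assignments, medoids)`` where assignments are 0-based medoid
    indices per point.  Small instances (at most ``EXACT_SUBSET_LIMIT``
    medoid subsets) are solved exactly by enumeration — PAM's single-swap
    neighborhood can stall at local optima there, and enumeration is
    cheaper anyway; larger instances use the deterministic PAM build+swap
    heuristic.  ``init_seed`` is accepted for interface stability but
    unused by the deterministic initialization.
    """
    from math import comb

    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == n:
        medoids = list(range(n))
    elif comb(n, k) <= EXACT_SUBSET_LIMIT:
        medoids = _exact_medoids(D, k)
    else:
        medoids = _pam_swap(D, _pam_build(D, k))
    med = np.asarray(medoids)
    assignments = med[np.argmin(D[:, med], axis=1)]
    return assignments, med


def pam_cost(D: np.ndarray, medoids: Sequence[int]) -> float:
    med = np.asarray(list(medoids))
    return float(np.min(np.asarray(D)[:, med], axis=1).sum())


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Per-k consensus matrices, final calls and model-selection diagnostics."""

    k_range: list[int]
    consensus: dict[int, pd.DataFrame]        # samples x samples in [0, 1]
    assignments: dict[int, pd.Series]         # cluster labels 1..k per sample
    cdf_grid: np.ndarray                      # common grid on [0, 1]
    cdf: dict[int, np.ndarray]
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int
    low_confidence: bool
    n_resamples: int
    p_item: float
    seed: int | None

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_range,
            "area": [self.area[k] for k in self.k_range],
            "delta_area": [self.delta_area[k] for k in self.k_range],
            "pac": [self.pac[k] for k in self.k_range],
            "chosen": [k == self.chosen_k for k in self.k_range],
        }).set_index("k")


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size (ties: by smallest member index)."""
    uniq = np.unique(labels)
    order = sorted(uniq, key=lambda c: (-(labels == c).sum(),
                                        int(np.nonzero(labels == c)[0][0])))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.asarray([mapping[c] for c in labels])


def consensus_cluster(
    expression: pd.DataFrame,
    features: Sequence[str] | None = None,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_resamples: int = 1000,
    p_item: float = 0.8,
    distance: str = "correlation",
    seed: int | None = 0,
    pac_lower: float = 0.1,
    pac_upper: float = 0.9,
) -> ConsensusResult:
    """Consensus clustering of samples over a feature gene set.

    Every resample uses the same subsample across all k (the reference
    implementation's convention).  Raises if some sample pair is never
    co-sampled (its consensus value would be undefined — increase
    ``n_resamples``).
    """
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k_range must start at 2 or higher")
    Dfull = DISTANCES[distance](expression, features).to_numpy()
    samples = list(expression.columns)
    n = len(samples)
    if max(k_range) >= n:
        raise ValueError("max k must be below the number of samples")
    m = int(np.ceil(p_item * n))
    rng = np.random.default_rng(seed)

    hits = {k: np.zeros((n, n)) for k in k_range}
    pair_counts = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        pair_counts[np.ix_(idx, idx)] += 1
        Dsub = Dfull[np.ix_(idx, idx)]
        for k in k_range:
            labels, _ = kmedoids(Dsub, k)
            same = labels[:, None] == labels[None, :]
            hits[k][np.ix_(idx, idx)] += same

    off_diag = ~np.eye(n, dtype=bool)
    if (pair_counts[off_diag] == 0).any():
        raise ValueError(
            "some sample pairs were never co-sampled; increase n_resamples"
        )

    grid = np.linspace(0.0, 1.0, 101)
    consensus, assignments, cdf, area, pac = {}, {}, {}, {}, {}
    for k in k_range:
        M = hits[k] / pair_counts
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)

        link = linkage(squareform(np.clip(1.0 - M, 0.0, None), checks=False),
                       method="average")
        raw = fcluster(link, t=k, criterion="maxclust")
        assignments[k] = pd.Series(_relabel_by_size(raw), index=samples,
                                   name=f"cluster_k{k}")

        vals = np.sort(M[np.triu_indices(n, 1)])
        cdf[k] = np.searchsorted(vals, grid, side="right") / vals.size
        area[k] = float(np.trapezoid(cdf[k], grid))
        pac[k] = float(
            np.searchsorted(vals, pac_upper, side="right") / vals.size
            - np.searchsorted(vals, pac_lower, side="right") / vals.size
        )

    delta_area: dict[int, float] = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta_area[k] = area[k]
        else:
            delta_area[k] = (area[k] - area[prev]) / area[prev] if area[prev] > 0 else 0.0
        prev = k

    chosen_k, low_confidence = _select_k(k_range, delta_area, pac)
    return ConsensusResult(
        k_range=k_range, consensus=consensus, assignments=assignments,
        cdf_grid=grid, cdf=cdf, area=area, delta_area=delta_area, pac=pac,
        chosen_k=chosen_k, low_confidence=low_confidence,
        n_resamples=n_resamples, p_item=p_item, seed=seed,
    )


def _select_k(k_range: Sequence[int], delta_area: dict[int, float],
              pac: dict[int, float], rel_threshold: float = 0.1,
              pac_confident: float = 0.2) -> tuple[int, bool]:
    ks = list(k_range)
    if len(ks) == 1:
        k = ks[0]
    else:
        eligible = [k for k in ks[1:] if delta_area[k] >= rel_threshold]
        k = max(eligible) if eligible else ks[0]
    return k, bool(pac[k] > pac_confident)


def select_k(result: ConsensusResult, rel_threshold: float = 0.1,
             pac_confident: float = 0.2) -> tuple[int, pd.DataFrame]:
    """Recommend k: the largest k whose relative delta-area gain is at least
    ``rel_threshold`` (elbow rule), with PAC reported alongside; the call is
    flagged low-confidence when the chosen k's PAC exceeds ``pac_confident``.
    Users may always override the recommendation."""
    k, low_conf = _select_k(result.k_range, result.delta_area, result.pac,
                            rel_threshold, pac_confident)
    report = result.report().copy()
    report["recommended"] = [kk == k for kk in result.k_range]
    report.attrs["low_confidence"] = low_conf
    return k, report
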