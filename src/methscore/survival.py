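"""Kaplan-Meier estimation, log-rank comparison and the maximally selected
rank-statistic cutpoint for dichotomizing a continuous score.

The cutpoint scan evaluates the standardized two-group log-rank statistic
z(c) = (O - E) / sqrt(V) at every candidate cut c — midpoints between
consecutive unique score values that leave at least a ``minprop`` fraction
of samples on each side — and returns the candidate maximizing |z| (ties
resolved towards the smaller cut).  Because the cut is selected to maximize
the statistic, the naive log-rank p-value at the chosen cut is
anti-conservative; results carry an explicit ``selection_biased`` flag and
an optional permutation-adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and equal length")
    if (t < 0).any() or np.isnan(t).any():
        raise ValueError("times must be non-negative and non-missing")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit estimate on the grid of distinct event times."""

    times: np.ndarray          # distinct event times, increasing
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    n_samples: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "n_risk": self.n_risk, "n_event": self.n_event,
            "survival": self.survival, "greenwood_var": self.variance,
        })


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator; tied events share their time."""
    t, e = _as_arrays(times, events)
    n = len(t)
    event_times = np.unique(t[e == 1])
    n_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    n_event = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=int)
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    # Greenwood: Var S(t) = S(t)^2 * sum d/(r(r-d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_event / (n_risk * (n_risk - n_event))
    terms = np.where(n_risk == n_event, np.inf, terms)
    gsum = np.cumsum(terms)
    with np.errstate(invalid="ignore"):
        var = np.where(surv > 0, surv**2 * gsum, 0.0)
    return KmCurve(event_times, n_risk, n_event, surv, var, n)


def median_survival(curve: KmCurve) -> float:
    """Smallest time with S(t) <= 0.5; NaN if the curve never reaches 0.5."""
    below = curve.survival <= 0.5
    if not below.any():
        return float("nan")
    return float(curve.times[np.argmax(below)])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_oe(t: np.ndarray, e: np.ndarray, member: np.ndarray
                ) -> tuple[float, float, float]:
    """Observed events, expected events and hypergeometric variance for one
    group (binary membership) — the building block of the two-group test."""
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for u in event_times:
        at_risk = t >= u
        r = at_risk.sum()
        r1 = (at_risk & member).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & member).sum()
        O += d1
        E += d * r1 / r
        if r > 1:
            V += d * (r1 / r) * (1 - r1 / r) * (r - d) / (r - 1)
    return float(O), float(E), float(V)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi2, df, p).

    Uses the standard observed-minus-expected statistic with the
    hypergeometric covariance at each distinct event time; df = k - 1.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 0.0, k - 1, 1.0

    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for u in event_times:
        at_risk = t >= u
        r = at_risk.sum()
        d = ((t == u) & (e == 1)).sum()
        r_i = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
        d_i = np.array([((t == u) & (e == 1) & (g == lab)).sum() for lab in labels],
                       dtype=float)
        OmE += d_i - d * r_i / r
        if r > 1:
            p_i = r_i / r
            V += (d * (r - d) / (r - 1)) * (np.diag(p_i) - np.outer(p_i, p_i))

    sub = slice(0, k - 1)
    Vs = V[sub, sub]
    try:
        chi2 = float(OmE[sub] @ np.linalg.solve(Vs, OmE[sub]))
    except np.linalg.LinAlgError:
        chi2 = float(OmE[sub] @ np.linalg.pinv(Vs) @ OmE[sub])
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, k - 1, p


# ---------------------------------------------------------------------------
# maximally selected rank statistic
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float               # standardized log-rank z at the cutpoint
    p_naive: float                 # 2-sided normal p; biased by selection
    selection_biased: bool
    scan: pd.DataFrame             # candidate, z, n_low, n_high
    n_low: int
    n_high: int
    p_permutation: float | None = None
    n_permutations: int = 0

    def groups(self, score: pd.Series, labels=("Low", "High")) -> pd.Series:
        """Dichotomize a score series at the cutpoint (low: score <= cut)."""
        return pd.Series(
            np.where(np.asarray(score, float) <= self.cutpoint, labels[0], labels[1]),
            index=getattr(score, "index", None), name="group",
        )


def _max_selected_z(score: np.ndarray, t: np.ndarray, e: np.ndarray,
                    candidates: np.ndarray) -> tuple[np.ndarray, int]:
    zs = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        member = score <= c
        O, E, V = _logrank_oe(t, e, member)
        zs[i] = (O - E) / np.sqrt(V) if V > 0 else 0.0
    best = int(np.argmax(np.abs(zs)))  # argmax takes the first (=smaller cut) on ties
    return zs, best


def find_cutpoint(score, times, events, minprop: float = 0.1,
                  n_permutations: int = 0, seed: int | None = None
                  ) -> CutpointResult:
    """Optimal survival cutpoint by the maximally selected log-rank statistic.

    Candidates are midpoints between consecutive unique score values whose
    induced split leaves at least ``ceil(minprop * n)`` samples on each
    side.  With ``n_permutations > 0`` a permutation-adjusted p-value for
    the selected statistic is computed by re-running the scan on permuted
    score vectors.
    """
    t, e = _as_arrays(times, events)
    s = np.asarray(score, dtype=float)
    if s.shape != t.shape:
        raise ValueError("score length mismatch")
    if e.sum() == 0:
        raise ValueError("no events; cutpoint undefined")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; cutpoint undefined")
    n = len(s)
    min_side = int(np.ceil(minprop * n))
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    n_low = np.array([(s <= c).sum() for c in mid])
    ok = (n_low >= min_side) & (n - n_low >= min_side)
    candidates = mid[ok]
    if candidates.size == 0:
        raise ValueError("no candidate cut satisfies the minprop constraint")

    zs, best = _max_selected_z(s, t, e, candidates)
    cut = float(candidates[best])
    z = float(zs[best])
    scan = pd.DataFrame({
        "candidate": candidates,
        "z": zs,
        "n_low": n_low[ok],
        "n_high": n - n_low[ok],
    })

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(s)
            pz, pbest = _max_selected_z(perm, t, e, candidates)
            if abs(pz[pbest]) >= abs(z):
                hits += 1
        p_perm = (1 + hits) / (n_permutations + 1)

    return CutpointResult(
        cutpoint=cut, statistic=z,
        p_naive=float(2 * stats.norm.sf(abs(z))),
        selection_biased=True, scan=scan,
        n_low=int((s <= cut).sum()), n_high=int((s > cut).sum()),
        p_permutation=p_perm, n_permutations=n_permutations,
    )
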