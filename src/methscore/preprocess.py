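"""Cohort cleaning: clinical filters, duplicate-gene collapsing, sample
alignment and per-gene standardization.

The clinical filters drop samples with unknown follow-up (missing survival
time), survival time shorter than ``min_days`` (default 30; exactly 30 days
is kept), or missing vital status.  Each exclusion is counted per rule; the
retained set is the intersection of the rules, so filter order never
matters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methscore")

MULTI_GENE_SEPARATORS = ("///", ";")


@dataclass
class CohortBundle:
    """Expression and clinical tables restricted to common samples, aligned."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    exclusion_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.clinical.index):
            raise ValueError("expression samples and clinical samples not aligned")


def filter_clinical_samples(
    clinical: pd.DataFrame, min_days: float = 30.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop samples with unusable follow-up.

    Rules (counted independently; a sample may violate several):
      * ``missing_time``  — os_time unknown
      * ``short_time``    — os_time < min_days (strictly; == min_days kept)
      * ``missing_status``— os_status unknown

    Raises if no sample survives.
    """
    time = pd.to_numeric(clinical["os_time"], errors="coerce")
    status = pd.to_numeric(clinical["os_status"], errors="coerce")
    missing_time = time.isna()
    short_time = time.notna() & (time < min_days)
    missing_status = status.isna()
    drop = missing_time | short_time | missing_status
    counts = {
        "missing_time": int(missing_time.sum()),
        "short_time": int(short_time.sum()),
        "missing_status": int(missing_status.sum()),
        "n_removed": int(drop.sum()),
        "n_kept": int((~drop).sum()),
    }
    kept = clinical.loc[~drop].copy()
    if kept.empty:
        raise ValueError("no samples survive the clinical filters")
    kept["os_time"] = time.loc[kept.index]
    kept["os_status"] = status.loc[kept.index].astype(int)
    logger.info("clinical filters: kept %d / %d samples (%s)", len(kept),
                len(clinical), counts)
    return kept, counts


def collapse_duplicate_genes(
    expression: pd.DataFrame,
    multi_gene_separators: Sequence[str] = MULTI_GENE_SEPARATORS,
) -> pd.DataFrame:
    """One row per gene symbol.

    Rows whose identifier names multiple genes (contains a separator such as
    ``///`` or ``;``) are removed first; remaining duplicate symbols are
    collapsed to the per-sample median across their rows.  Row order follows
    first occurrence of each kept symbol.
    """
    idx = expression.index.astype(str)
    multi = np.zeros(len(idx), dtype=bool)
    for sep in multi_gene_separators:
        multi |= idx.str.contains(sep, regex=False)
    if multi.any():
        logger.info("removed %d multi-gene rows", int(multi.sum()))
    kept = expression.loc[~multi]
    if not kept.index.duplicated().any():
        return kept.copy()
    order = kept.index.drop_duplicates()
    collapsed = kept.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def align_cohort(expression: pd.DataFrame, clinical: pd.DataFrame) -> CohortBundle:
    """Intersect and align expression columns with clinical rows.

    Sample order in the bundle is the sorted common-sample list, so the
    result is independent of input orderings.  Losses on both sides are
    counted in the exclusion log.
    """
    common = sorted(set(expression.columns) & set(clinical.index))
    if not common:
        raise ValueError("expression and clinical tables share no samples")
    log = {
        "expression_only": int(expression.shape[1] - len(common)),
        "clinical_only": int(len(clinical) - len(common)),
        "n_common": len(common),
    }
    if log["expression_only"] or log["clinical_only"]:
        logger.info("align_cohort: %s", log)
    return CohortBundle(expression[common].copy(), clinical.loc[common].copy(), log)


def zscore_genes(expression: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-gene standardization to mean 0, SD 1 (population SD by default).

    Zero-variance genes cannot be standardized and are dropped with a
    warning.  Applying the transform twice is a no-op (idempotent up to
    floating-point error).
    """
    values = expression.to_numpy(float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance genes before z-scoring",
            stacklevel=2,
        )
        expression = expression.loc[~flat]
        values, mu, sd = values[~flat], mu[~flat], sd[~flat]
    z = (values - mu) / sd
    return pd.DataFrame(z, index=expression.index.copy(),
                        columns=expression.columns.copy())
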