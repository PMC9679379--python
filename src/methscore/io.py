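"""Readers and writers for the tabular formats the pipeline touches.

Conventions
-----------
* Expression matrices are :class:`pandas.DataFrame` objects with gene symbols
  as the index (rows) and sample identifiers as columns, values on a log2
  scale.  Duplicate gene rows are tolerated at load time (collapsing is a
  preprocessing step) but duplicate sample columns are an error.
* Clinical tables are DataFrames indexed by ``sample_id`` with at least
  ``os_time`` (days, >= 0) and ``os_status`` (event indicator in {0, 1}).
  Unknown survival values are kept as missing at load time; dropping them is
  the preprocessing module's job.
* Gene sets use the standard GMT dialect: ``name <tab> description <tab>
  gene1 <tab> gene2 ...``.
* Mutation calls are a "MAF-lite" long table ``sample_id, gene,
  variant_class``; CNV calls are a genes x samples matrix of GISTIC-style
  5-level integer codes {-2, -1, 0, +1, +2}.

Loaders never silently drop rows: every exclusion or anomaly is counted in
the returned :class:`LoadReport` and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methscore")

#: fixed float format used by every writer so reruns are byte-identical
FLOAT_FORMAT = "%.10g"

REQUIRED_CLINICAL_COLUMNS = ("sample_id", "os_time", "os_status")
CNV_CODES = (-2, -1, 0, 1, 2)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class LoadReport:
    """Accounting attached to a loader call: nothing is dropped silently."""

    n_rows: int = 0
    n_duplicate_gene_symbols: int = 0
    n_duplicate_records_dropped: int = 0
    n_missing_values: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named, non-empty gene sets."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if len(gs.genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def as_dict(self) -> dict[str, list[str]]:
        return {name: list(gs.genes) for name, gs in self.sets.items()}


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    sep: str | None = None,
    log2_offset: float | None = None,
    impute_median: bool = False,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a genes x samples expression matrix.

    Parameters
    ----------
    path
        TSV/CSV file; first column holds gene identifiers, header holds
        sample identifiers.
    log2_offset
        If given, the matrix is assumed raw and ``log2(x + log2_offset)`` is
        applied (TCGA RNA-seq conventionally uses an offset of 1).  By
        default values are assumed already log2-transformed.
    impute_median
        Missing cells are refused by default; with this flag they are filled
        with the per-gene median (counted in the report).

    Returns
    -------
    (matrix, report)
        ``matrix`` keeps duplicate gene rows (collapsing belongs to
        preprocessing); the report counts duplicated symbols.
    """
    path = Path(path)
    delim = _sep_for(path, sep)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(delim)[1:]
    seen_dups = sorted({h for h in header if header.count(h) > 1})
    if seen_dups:
        # pandas would silently mangle duplicate headers, so check the raw line
        raise FormatError(f"{path}: duplicated sample identifiers: {seen_dups}")
    df = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")

    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"{path}: non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
        values[col] = converted

    report = LoadReport(n_rows=values.shape[0])
    report.n_missing_values = int(values.isna().to_numpy().sum())
    if report.n_missing_values:
        if not impute_median:
            raise FormatError(
                f"{path}: {report.n_missing_values} missing expression values "
                "(pass impute_median=True to fill with per-gene medians)"
            )
        values = values.T.fillna(values.median(axis=1)).T
        report.notes.append(
            f"imputed {report.n_missing_values} missing cells with per-gene medians"
        )

    values.index = values.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()

    dup_symbols = values.index[values.index.duplicated()].unique()
    report.n_duplicate_gene_symbols = len(dup_symbols)
    if len(dup_symbols):
        logger.warning(
            "%s: %d duplicated gene symbols (will be median-collapsed in "
            "preprocessing)", path, len(dup_symbols)
        )

    if log2_offset is not None:
        if (values.to_numpy() + log2_offset <= 0).any():
            raise FormatError(f"{path}: log2(x + {log2_offset}) undefined for some cells")
        values = np.log2(values + log2_offset)
        report.notes.append(f"applied log2(x + {log2_offset})")

    return values, report


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path, sep: str | None = None) -> tuple[pd.DataFrame, LoadReport]:
    """Read a clinical table with required columns sample_id, os_time, os_status.

    Missing survival values are kept as NaN (the preprocessing filters drop
    them with accounting); an ``os_status`` outside {0, 1, missing} is a
    format error, as is a missing required column or a duplicated sample id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required clinical columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df["sample_id"][df["sample_id"].duplicated()]))
        raise FormatError(f"{path}: duplicated sample_id values: {dups}")

    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    if (df["os_time"].dropna() < 0).any():
        raise FormatError(f"{path}: negative os_time values")
    status = pd.to_numeric(df["os_status"], errors="coerce")
    bad = status.dropna()[~status.dropna().isin([0, 1])]
    if len(bad):
        raise FormatError(
            f"{path}: os_status must be 0/1 (or missing); offending values: "
            f"{sorted(set(bad))}"
        )
    df["os_status"] = status

    df = df.set_index("sample_id")
    report = LoadReport(n_rows=len(df))
    report.n_missing_values = int(df[["os_time", "os_status"]].isna().to_numpy().sum())
    return df, report


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into an ordered :class:`GeneSetCollection`.

    Duplicate genes within a set are deduplicated (first occurrence wins);
    a line with fewer than three fields, a duplicated set name, or an empty
    membership is an error naming the line.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, description = fields[0].strip(), fields[1].strip()
            genes = list(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicated set name {name!r}")
            sets[name] = GeneSet(name, description, tuple(genes))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gs in collection:
            handle.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# mutation / CNV
# ---------------------------------------------------------------------------

def read_maf(path: str | Path, sep: str | None = None) -> tuple[pd.DataFrame, LoadReport]:
    """Read a MAF-lite mutation table (sample_id, gene, variant_class).

    Exact duplicate (sample, gene, variant_class) triples are dropped with a
    count in the report; a sample mutated twice in a gene with different
    variant classes keeps both rows (frequency counting dedups per gene).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    missing = [c for c in ("sample_id", "gene", "variant_class") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing MAF-lite columns: {missing}")
    for col in ("sample_id", "gene", "variant_class"):
        df[col] = df[col].astype(str).str.strip()
    n0 = len(df)
    df = df.drop_duplicates(subset=["sample_id", "gene", "variant_class"]).reset_index(drop=True)
    report = LoadReport(n_rows=len(df), n_duplicate_records_dropped=n0 - len(df))
    if report.n_duplicate_records_dropped:
        logger.warning("%s: dropped %d duplicate mutation records", path,
                       report.n_duplicate_records_dropped)
    return df, report


def read_cnv(path: str | Path, sep: str | None = None) -> tuple[pd.DataFrame, LoadReport]:
    """Read a genes x samples CNV matrix of 5-level calls in {-2..+2}."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    arr = df.to_numpy()
    if not np.isin(arr, CNV_CODES).all():
        bad = sorted(set(arr.ravel()) - set(CNV_CODES))
        raise FormatError(f"{path}: CNV calls outside {{-2..+2}}: {bad}")
    df = df.astype(int)
    df.index = df.index.astype(str).str.strip()
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicated gene or sample identifiers in CNV table")
    return df, LoadReport(n_rows=len(df))


# ---------------------------------------------------------------------------
# generic writer
# ---------------------------------------------------------------------------

def write_table(result: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV with a fixed float format.

    Column and row order are preserved as given by the caller (callers are
    responsible for producing deterministic orders), and floats are printed
    at fixed precision so identical results are byte-identical on disk.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = out.index.name or "gene"
    write_table(out, path)
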