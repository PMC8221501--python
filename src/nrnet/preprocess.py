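"""Reading and preparation of cBioPortal-style expression cohorts.

Expression tables are tab-separated, genes in rows and samples in columns,
with a gene-symbol column (``Hugo_Symbol`` by default).  Clinical tables
carry one row per patient with a PAM50 subtype column.  The canonical
in-memory container is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` plus a median-centring flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError

logger = logging.getLogger(__name__)

#: tokens accepted as missing values in expression cells
NA_TOKENS = {"", "na", "nan", "null", "n/a"}


class Subtype(str, Enum):
    """PAM50 molecular subtypes retained by the pipeline.

    Claudin-low and normal-like samples are mapped to ``Other`` and excluded
    from pairwise cohorts.
    """

    LuminalA = "LuminalA"
    LuminalB = "LuminalB"
    Her2 = "Her2"
    Basal = "Basal"
    Other = "Other"


#: case-insensitive aliases seen in cBioPortal clinical files
_SUBTYPE_ALIASES = {
    "luma": Subtype.LuminalA,
    "luminala": Subtype.LuminalA,
    "luminal a": Subtype.LuminalA,
    "lumb": Subtype.LuminalB,
    "luminalb": Subtype.LuminalB,
    "luminal b": Subtype.LuminalB,
    "her2": Subtype.Her2,
    "her2-enriched": Subtype.Her2,
    "erbb2": Subtype.Her2,
    "basal": Subtype.Basal,
    "basal-like": Subtype.Basal,
    "basallike": Subtype.Basal,
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with identifier bookkeeping.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    centred
        True once every gene row has had its median subtracted.
    """

    values: pd.DataFrame
    centred: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample identifiers in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleAnnotation:
    sample_id: str
    subtype: Subtype


@dataclass
class GeneList:
    """Ordered, unique gene symbols with an optional role per symbol."""

    symbols: list[str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise DataError("gene list contains duplicate symbols")


def read_expression_table(
    path: str | Path,
    dialect: str = "cbioportal_tsv",
    symbol_column: str = "Hugo_Symbol",
) -> ExpressionMatrix:
    """Parse a tab-separated genes x samples expression table.

    The first column (or ``symbol_column`` if present in the header) holds
    gene symbols; an ``Entrez_Gene_Id`` column is ignored; every remaining
    column is one sample.  Rows with an empty symbol are dropped.  Duplicate
    symbols keep the highest-variance row (the most informative probe) with
    a logged warning.  A non-numeric token outside the accepted missing-value
    spellings is a parse error naming its row and column.
    """
    if dialect != "cbioportal_tsv":
        raise ConfigurationError(f"unknown expression dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"expression file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if raw.shape[1] < 2:
        raise ParseError(
            f"{path.name}: expected a gene-symbol column plus sample columns, "
            f"got {raw.shape[1]} column(s)"
        )
    header = list(raw.columns)
    sym_col = symbol_column if symbol_column in header else header[0]
    sample_cols = [c for c in header if c not in (sym_col, "Entrez_Gene_Id")]
    if not sample_cols:
        raise ParseError(f"{path.name}: no sample columns found in header")

    symbols = raw[sym_col].fillna("").str.strip()
    keep = symbols != ""
    dropped_blank = int((~keep).sum())
    if dropped_blank:
        logger.warning("%s: dropped %d rows with empty gene symbol", path.name, dropped_blank)
    raw = raw.loc[keep]
    symbols = symbols.loc[keep]

    numeric = pd.DataFrame(index=raw.index, columns=sample_cols, dtype=float)
    for col in sample_cols:
        cells = raw[col].fillna("").str.strip()
        converted = pd.to_numeric(cells, errors="coerce")
        bad = converted.isna() & ~cells.str.lower().isin(NA_TOKENS)
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path.name}: non-numeric value {cells.loc[row]!r} at "
                f"gene {symbols.loc[row]!r}, sample column {col!r}"
            )
        numeric[col] = converted.astype(float)
    numeric.index = pd.Index(symbols.values, name="gene")

    if numeric.index.has_duplicates:
        dupes = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning(
            "%s: %d duplicated gene symbol(s) (%s); keeping highest-variance row each",
            path.name, len(dupes), ", ".join(dupes[:5]),
        )
        variances = numeric.var(axis=1, skipna=True).fillna(-np.inf)
        seen: dict[str, tuple[float, int]] = {}
        for pos, (sym, var) in enumerate(zip(numeric.index, variances.values)):
            if sym not in seen or var > seen[sym][0]:
                seen[sym] = (var, pos)
        keep_pos = sorted(p for _, p in seen.values())
        numeric = numeric.iloc[keep_pos]

    return ExpressionMatrix(values=numeric, centred=False)


def write_expression_table(m: ExpressionMatrix, path: str | Path,
                           symbol_column: str = "Hugo_Symbol") -> None:
    """Serialise the matrix in the same TSV layout ``read_expression_table`` reads."""
    out = m.values.copy()
    out.insert(0, symbol_column, out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_subtype_labels(
    path: str | Path,
    sample_column: str = "PATIENT_ID",
    subtype_column: str = "CLAUDIN_SUBTYPE",
) -> list[SampleAnnotation]:
    """Read PAM50 subtype labels from a clinical TSV.

    Unknown subtype strings, claudin-low and normal-like all map to
    :attr:`Subtype.Other`, which downstream cohort construction excludes.
    Lines starting with ``#`` (cBioPortal metadata headers) are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"clinical file not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (sample_column, subtype_column):
        if col not in table.columns:
            raise ConfigurationError(
                f"{path.name}: required column {col!r} not found "
                f"(available: {', '.join(table.columns)})"
            )
    annotations: list[SampleAnnotation] = []
    seen: set[str] = set()
    for _, row in table.iterrows():
        sid = str(row[sample_column]).strip()
        if not sid or sid.lower() in NA_TOKENS:
            continue
        if sid in seen:
            raise DataError(f"{path.name}: duplicated sample id {sid!r}")
        seen.add(sid)
        label = str(row[subtype_column]).strip().lower()
        annotations.append(SampleAnnotation(sid, _SUBTYPE_ALIASES.get(label, Subtype.Other)))
    return annotations


def read_gene_list(path: str | Path) -> GeneList:
    """Read one gene symbol per line; ``#`` starts a comment.

    An optional second whitespace-separated token per line is kept as the
    gene's role (e.g. ``NR`` or ``coregulator``).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"gene list not found: {path}")
    symbols: list[str] = []
    roles: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        sym = parts[0]
        if sym in symbols:
            logger.warning("%s: duplicate symbol %s ignored", path.name, sym)
            continue
        symbols.append(sym)
        if len(parts) > 1:
            roles[sym] = parts[1]
    return GeneList(symbols=symbols, roles=roles)


def restrict_to_gene_list(
    m: ExpressionMatrix, genes: GeneList
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep only rows whose symbol is in ``genes``, in the list's order.

    Returns the restricted matrix together with the symbols from the list
    that were absent from the matrix, so callers can report availability
    (e.g. "171 of 178 genes available").
    """
    present = [g for g in genes.symbols if g in m.values.index]
    absent = [g for g in genes.symbols if g not in m.values.index]
    if not present:
        raise DataError("gene list and expression matrix share no genes")
    if absent:
        logger.info("gene-list restriction: %d of %d genes absent (%s)",
                    len(absent), len(genes.symbols), ", ".join(absent[:10]))
    return ExpressionMatrix(values=m.values.loc[present], centred=m.centred), absent


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's median (missing values ignored).

    Idempotent: centring a centred matrix changes nothing beyond floating
    point noise, and the ``centred`` flag makes repeated application cheap
    to detect.
    """
    values = m.values
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        bad = list(values.index[all_missing])
        raise DataError(f"gene(s) with all values missing: {', '.join(bad[:10])}")
    medians = values.median(axis=1, skipna=True)
    return ExpressionMatrix(values=values.sub(medians, axis=0), centred=True)


def build_pairwise_cohort(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    a: Subtype,
    b: Subtype,
    min_samples: int = 10,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Column-subset the matrix to samples annotated with subtype ``a`` or ``b``.

    Samples present in the matrix but lacking an annotation are dropped
    (their count is logged).  Each arm must reach ``min_samples``.
    """
    if a == b:
        raise ConfigurationError("pairwise cohort needs two distinct subtypes")
    by_id = {ann.sample_id: ann for ann in annotations}
    kept_cols: list[str] = []
    kept_ann: list[SampleAnnotation] = []
    unannotated = 0
    for sid in m.sample_ids:
        ann = by_id.get(sid)
        if ann is None:
            unannotated += 1
            continue
        if ann.subtype in (a, b):
            kept_cols.append(sid)
            kept_ann.append(ann)
    if unannotated:
        logger.info("pairwise cohort %s vs %s: %d unannotated samples dropped",
                    a.value, b.value, unannotated)
    n_a = sum(1 for ann in kept_ann if ann.subtype == a)
    n_b = sum(1 for ann in kept_ann if ann.subtype == b)
    for subtype, n in ((a, n_a), (b, n_b)):
        if n < min_samples:
            raise DataError(
                f"subtype {subtype.value} has {n} annotated samples in the matrix "
                f"(minimum {min_samples})"
            )
    return ExpressionMatrix(values=m.values[kept_cols], centred=m.centred), kept_ann
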