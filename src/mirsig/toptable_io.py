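"""Read heterogeneous differential-expression "top-table" summaries.

Microarray differential-expression results circulate as per-gene summary
tables (symbol, log2 fold-change, nominal p, BH-adjusted p) whose column
names differ by tool and platform ("logFC" vs "log2FC", "adj.P.Val" vs
"padj", ...).  This module resolves those dialects against a synonym list
and standardizes every table to a common schema so downstream thresholding,
consensus construction and enrichment can run identically across cohorts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguousColumnError, EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

CANONICAL_FIELDS = ("symbol", "log2fc", "pvalue", "fdr", "title")
REQUIRED_FIELDS = ("symbol", "log2fc", "fdr")

#: Adjusted p-values of exactly 0 are floored here so -log10 stays finite.
FDR_FLOOR = 1e-300

# Synonyms are matched after lowercasing and stripping non-alphanumerics,
# so "adj.P.Val", "Adj_P_Val" and "adjPVal" all resolve to "fdr".
_SYNONYMS: dict[str, frozenset[str]] = {
    "symbol": frozenset(
        {"symbol", "gene", "genesymbol", "genename", "hgncsymbol", "geneid"}
    ),
    "log2fc": frozenset(
        {"log2fc", "logfc", "log2foldchange", "lfc", "log2ratio", "foldchangelog2"}
    ),
    "pvalue": frozenset({"pvalue", "pval", "p", "nominalp", "rawp"}),
    "fdr": frozenset(
        {"fdr", "adjpval", "adjp", "padj", "qvalue", "qval", "adjustedp",
         "adjustedpvalue", "fdradjustedp", "bhfdr", "fdradjp"}
    ),
    "title": frozenset({"title", "genetitle", "description", "genedescription"}),
}

_NORM_RE = re.compile(r"[^a-z0-9]+")


def _normalize(name: str) -> str:
    return _NORM_RE.sub("", str(name).strip().lower())


@dataclass(frozen=True)
class SchemaMap:
    """Resolution of a raw header against the canonical schema."""

    mapping: Mapping[str, str]
    unresolved: tuple[str, ...]

    def require_complete(self) -> None:
        if self.unresolved:
            raise SchemaError(
                "could not resolve required column(s): " + ", ".join(self.unresolved)
            )


def standardize_schema(raw_header: Sequence[str]) -> SchemaMap:
    """Map raw column names onto the canonical top-table fields.

    Returns a :class:`SchemaMap` whose ``mapping`` is canonical-field ->
    source-column; required fields that matched nothing are listed in
    ``unresolved``.  Two source columns matching the same canonical field
    raise :class:`AmbiguousColumnError`.
    """
    if len(raw_header) == 0:
        raise SchemaError("empty header")
    mapping: dict[str, str] = {}
    for col in raw_header:
        norm = _normalize(col)
        for canon, syns in _SYNONYMS.items():
            if norm in syns:
                if canon in mapping and mapping[canon] != col:
                    raise AmbiguousColumnError(
                        f"columns {mapping[canon]!r} and {col!r} both map to "
                        f"{canon!r}"
                    )
                mapping[canon] = col
    unresolved = tuple(f for f in REQUIRED_FIELDS if f not in mapping)
    return SchemaMap(mapping=mapping, unresolved=unresolved)


@dataclass
class DETable:
    """One cohort's standardized differential-expression summary.

    ``df`` holds the canonical columns ``symbol, log2fc, pvalue, fdr, title``
    (pvalue/title may be NaN).  ``provenance`` records the source path and
    the column mapping used; ``n_dropped`` counts rows discarded at read
    time for non-numeric or out-of-range statistics.
    """

    dataset_id: str
    disease: str
    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def symbols(self) -> pd.Series:
        return self.df["symbol"]

    def copy(self) -> "DETable":
        return DETable(
            dataset_id=self.dataset_id,
            disease=self.disease,
            df=self.df.copy(),
            provenance=dict(self.provenance),
            n_dropped=self.n_dropped,
        )


def _coerce_frame(raw: pd.DataFrame, mapping: Mapping[str, str]) -> tuple[pd.DataFrame, int]:
    df = pd.DataFrame(index=raw.index)
    df["symbol"] = raw[mapping["symbol"]].astype(str).str.strip().str.upper()
    df["log2fc"] = pd.to_numeric(raw[mapping["log2fc"]], errors="coerce")
    df["pvalue"] = (
        pd.to_numeric(raw[mapping["pvalue"]], errors="coerce")
        if "pvalue" in mapping
        else np.nan
    )
    df["fdr"] = pd.to_numeric(raw[mapping["fdr"]], errors="coerce")
    df["title"] = (
        raw[mapping["title"]].astype(str) if "title" in mapping else ""
    )

    bad_symbol = df["symbol"].isin({"", "NAN", "NONE"})
    bad_lfc = ~np.isfinite(df["log2fc"])
    bad_fdr = df["fdr"].isna() | (df["fdr"] < 0) | (df["fdr"] > 1)
    drop = bad_symbol | bad_lfc | bad_fdr
    n_dropped = int(drop.sum())
    df = df.loc[~drop].reset_index(drop=True)
    # nominal p is optional: out-of-range values become NaN rather than drops
    df.loc[(df["pvalue"] < 0) | (df["pvalue"] > 1), "pvalue"] = np.nan
    df.loc[df["fdr"] == 0, "fdr"] = FDR_FLOOR
    return df, n_dropped


def read_toptable(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dataset_id: str = "",
    disease: str = "",
    sep: str | None = None,
    sheet: str | int = 0,
) -> DETable:
    """Read a delimited-text or XLSX top-table into a :class:`DETable`.

    The delimiter is sniffed from the extension (.csv -> comma, .xlsx ->
    spreadsheet, anything else -> tab) unless ``sep`` is given.  When
    ``column_map`` is omitted the header is resolved with
    :func:`standardize_schema`; unresolved required columns raise
    :class:`SchemaError`.  Rows with non-numeric log2fc/fdr, out-of-range
    fdr, or empty symbols are dropped and counted in ``n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        raw = pd.read_excel(path, sheet_name=sheet, dtype=str)
    else:
        use_sep = sep if sep is not None else ("," if suffix == ".csv" else "\t")
        try:
            raw = pd.read_csv(path, sep=use_sep, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise EmptyInputError(f"{path}: no columns or rows") from exc
    if raw.shape[0] == 0:
        raise EmptyInputError(f"{path}: header only, no data rows")

    if column_map is None:
        schema = standardize_schema(list(raw.columns))
        schema.require_complete()
        mapping = dict(schema.mapping)
    else:
        mapping = dict(column_map)
        missing = [f for f in REQUIRED_FIELDS if f not in mapping]
        if missing:
            raise SchemaError("column_map lacks required field(s): " + ", ".join(missing))
        absent = [c for c in mapping.values() if c not in raw.columns]
        if absent:
            raise SchemaError("mapped column(s) absent from file: " + ", ".join(absent))

    df, n_dropped = _coerce_frame(raw, mapping)
    if n_dropped:
        logger.info("%s: dropped %d unusable row(s)", path.name, n_dropped)
    return DETable(
        dataset_id=dataset_id or path.stem,
        disease=disease,
        df=df,
        provenance={"source": str(path), "column_map": mapping},
        n_dropped=n_dropped,
    )


def from_frame(
    df: pd.DataFrame,
    dataset_id: str,
    disease: str = "",
    provenance: dict | None = None,
) -> DETable:
    """Wrap an in-memory frame (canonical columns) as a :class:`DETable`."""
    out = pd.DataFrame(
        {
            "symbol": df["symbol"].astype(str).str.strip().str.upper(),
            "log2fc": pd.to_numeric(df["log2fc"]),
            "pvalue": pd.to_numeric(df["pvalue"]) if "pvalue" in df else np.nan,
            "fdr": pd.to_numeric(df["fdr"]).clip(lower=FDR_FLOOR),
            "title": df["title"].astype(str) if "title" in df else "",
        }
    ).reset_index(drop=True)
    return DETable(dataset_id, disease, out, provenance or {"source": "in-memory"})


def write_toptable(table: DETable, path: str | Path) -> Path:
    """Write the standardized schema as TSV (round-trips through read)."""
    path = Path(path)
    table.df.to_csv(path, sep="\t", index=False, columns=list(CANONICAL_FIELDS))
    return path
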