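"""Gene-label curation: probe filtering, composite cleaning, deduplication.

Microarray summaries mix true gene symbols with probe identifiers
("238604_at"), placeholder labels ("---") and composite multi-mapped labels
("ABCA6 /// ABCA9").  Curation keeps one valid symbol per gene so ranked
lists and set operations are well defined.  Provisional annotations (LOC /
LINC loci, pseudogenes) are retained but flagged for cautious downstream
interpretation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .toptable_io import DETable

logger = logging.getLogger(__name__)

DEFAULT_SEPARATORS = ("///", ";", ",")

_PLACEHOLDERS = {"", "-", "--", "---", "NA", "N/A", "NAN", "NONE", "NULL"}
_NUMERIC_RE = re.compile(r"^\d+(\.\d+)?$")
_PROVISIONAL_RE = re.compile(r"^(LOC\d+|LINC\d+)$|\dP\d+$")


def is_valid_symbol(label: str) -> bool:
    """True for labels usable as gene symbols.

    Rejects probe-style identifiers ending in "_at", purely numeric labels,
    and empty/placeholder labels.  LOC/LINC and pseudogene labels are valid
    (they carry a provisional flag instead, see :func:`is_provisional`).
    """
    s = str(label).strip().upper()
    if s in _PLACEHOLDERS:
        return False
    if s.endswith("_AT"):
        return False
    if _NUMERIC_RE.match(s):
        return False
    return True


def is_provisional(symbol: str) -> bool:
    """Flag locus-based provisional annotations and pseudogene-style labels."""
    return bool(_PROVISIONAL_RE.search(str(symbol).strip().upper()))


def clean_composite_label(
    label: str, separators: Sequence[str] = DEFAULT_SEPARATORS
) -> str | None:
    """Resolve a multi-mapped label to its first valid token, else None."""
    tokens = [str(label)]
    for sep in separators:
        tokens = [part for tok in tokens for part in tok.split(sep)]
    for tok in tokens:
        tok = tok.strip().upper()
        if tok and is_valid_symbol(tok):
            return tok
    return None


@dataclass
class CurationReport:
    """Counts of what curation removed or rewrote, for the audit trail."""

    dataset_id: str
    n_input: int
    n_composite_resolved: int
    n_invalid_removed: int
    n_duplicates_removed: int
    n_output: int
    n_provisional: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def deduplicate(table: DETable) -> DETable:
    """Keep one record per symbol: smallest FDR, then largest |log2fc|,
    then first occurrence.  Idempotent; never synthesizes values."""
    df = table.df.reset_index(drop=True)
    order = (
        df.assign(_abs=df["log2fc"].abs(), _pos=np.arange(len(df)))
        .sort_values(["fdr", "_abs", "_pos"], ascending=[True, False, True],
                     kind="stable")
    )
    keep = order.drop_duplicates("symbol", keep="first").sort_values("_pos")
    out = table.copy()
    out.df = keep.drop(columns=["_abs", "_pos"]).reset_index(drop=True)
    return out


def curate(
    table: DETable, separators: Sequence[str] = DEFAULT_SEPARATORS
) -> tuple[DETable, CurationReport]:
    """Full curation pass: composite cleaning -> validity filter -> dedup.

    Returns the curated table (with a boolean ``provisional`` column) and a
    :class:`CurationReport` of counts.
    """
    df = table.df.copy().reset_index(drop=True)
    n_input = len(df)

    has_sep = df["symbol"].apply(
        lambda s: any(sep in s for sep in separators)
    )
    resolved = df.loc[has_sep, "symbol"].apply(
        lambda s: clean_composite_label(s, separators)
    )
    n_composite_resolved = int(resolved.notna().sum())
    df.loc[has_sep, "symbol"] = resolved

    valid = df["symbol"].notna() & df["symbol"].apply(is_valid_symbol)
    n_invalid = int((~valid).sum())
    df = df.loc[valid].reset_index(drop=True)

    cur = table.copy()
    cur.df = df
    deduped = deduplicate(cur)
    n_dupes = len(df) - len(deduped.df)
    deduped.df["provisional"] = deduped.df["symbol"].apply(is_provisional)

    report = CurationReport(
        dataset_id=table.dataset_id,
        n_input=n_input,
        n_composite_resolved=n_composite_resolved,
        n_invalid_removed=n_invalid,
        n_duplicates_removed=n_dupes,
        n_output=len(deduped.df),
        n_provisional=int(deduped.df["provisional"].sum()),
    )
    logger.info(
        "%s: curation kept %d/%d records (%d invalid, %d duplicates removed)",
        table.dataset_id, report.n_output, n_input, n_invalid, n_dupes,
    )
    return deduped, report


def write_audit(reports: Iterable[CurationReport], path: str | Path) -> Path:
    """Write the curation audit table (one row per cohort) as TSV."""
    path = Path(path)
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
    return path
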