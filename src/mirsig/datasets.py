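"""Bundled example inputs: published top-20 gene report tables.

Four small per-cohort top-gene tables (top 10 upregulated plus top 10
downregulated, ranked by FDR) as publicly reported for the corresponding
GEO cohorts: GSE50006 and GSE31048 (chronic lymphocytic leukemia vs
healthy), GSE7116 and GSE27838 (multiple myeloma vs healthy, the latter a
low-signal cohort where only PRKCI survives FDR < 0.05).  They serve as
realistic, human-scale inputs for examples and for checking the harmonized
filter against known outcomes; they are reporting excerpts, not the full
differential-expression tables.
"""

from __future__ import annotations

from importlib import resources

from .toptable_io import DETable, read_toptable

ACCESSIONS = ("GSE50006", "GSE31048", "GSE7116", "GSE27838")

_DISEASE = {
    "GSE50006": "CLL",
    "GSE31048": "CLL",
    "GSE7116": "MM",
    "GSE27838": "MM",
}


def load_printed_top20(accession: str) -> DETable:
    """Load one bundled top-20 report table as a standardized DETable."""
    acc = accession.upper()
    if acc not in ACCESSIONS:
        raise KeyError(f"unknown accession {accession!r}; have {ACCESSIONS}")
    ref = resources.files("mirsig.data") / f"{acc.lower()}_top20.tsv"
    with resources.as_file(ref) as path:
        return read_toptable(path, dataset_id=acc, disease=_DISEASE[acc])
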