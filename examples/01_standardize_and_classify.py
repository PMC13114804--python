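"""Standardize published report tables and apply the harmonized filter.

Loads the four bundled per-cohort top-20 gene tables (top-table dialect
with 'Gene'/'logFC'/'adj.P.Val' headers), standardizes them to the common
schema, and classifies each gene under FDR < 0.05 and |log2FC| >= 1.
The low-signal cohort GSE27838 keeps a single significant gene (PRKCI),
so its report falls back to FDR-ranked labeling.
"""

from mirsig.datasets import ACCESSIONS, load_printed_top20
from mirsig.deg_classification import significant_sets, top_ranked

for accession in ACCESSIONS:
    table = load_printed_top20(accession)
    sets = significant_sets(table)
    n_up, n_down, total = sets.counts
    print(f"{accession}: {n_up} up / {n_down} down / {total} significant "
          f"of {len(table)} reported genes")

print()
low_signal = load_printed_top20("GSE27838")
blocks = top_ranked(low_signal, n_per_direction=3, mode="fdr_rank_fallback")
print("GSE27838 top genes by FDR ranking (fallback labeling):")
print(blocks["combined"][["symbol", "log2fc", "fdr", "direction"]]
      .to_string(index=False))
print("\nOnly PRKCI clears FDR < 0.05 here; the other labels are "
      "FDR-ranked candidates, not significant calls.")
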