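"""Hypergeometric over-representation analysis with BH correction.

For a signature of n genes drawn from a universe of N, and a regulon of K
validated targets within that universe, the probability of observing at
least k overlapping genes under random sampling without replacement is the
upper tail of Hypergeometric(N, K, n) — equivalently a one-sided Fisher
exact test on the 2x2 table.  Each signature is tested against every
regulon in the library; BH correction is applied within the signature
(regulons tested for one signature form one family), and results are
ranked by adjusted significance and effect size.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MirsigError
from .target_library import TargetLibrary, Universe

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

RESULT_COLUMNS = (
    "mirna", "k", "n", "K", "N", "pvalue", "fdr", "ratio",
    "overlap", "significant", "small_set",
)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the ORA tail probability.

    Arguments follow the 2x2 convention: k overlap, K regulon size, n
    signature size, N universe size.  Bounds are validated; the survival
    function is evaluated by scipy in a numerically stable way and floored
    at 1e-300 so downstream logs stay finite.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise MirsigError(f"invalid margins: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise MirsigError(f"invalid overlap k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, P_FLOOR))


def enrichment_ratio(k: int, K: int, n: int, N: int) -> float:
    """Observed over expected overlap fraction: (k/n) / (K/N)."""
    if n <= 0 or K <= 0:
        raise MirsigError(f"enrichment ratio undefined for n={n}, K={K}")
    return (k / n) / (K / N)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise MirsigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_signature(
    genes: Iterable[str],
    lib: TargetLibrary,
    universe: Universe,
    alpha: float = 0.05,
    k_min: int = 3,
    K_min: int = 5,
) -> pd.DataFrame:
    """Test one gene signature against every regulon in the library.

    Returns one row per regulon with the contingency counts, one-sided
    hypergeometric p, BH-adjusted FDR (family = all regulons tested for
    this signature), enrichment ratio and the overlapping symbols, ranked
    by (fdr asc, k desc, ratio desc, miRNA id).  Results whose k or K fall
    below the configured floors carry a ``small_set`` caution flag — they
    are flagged, never dropped.  Genes outside the universe are dropped
    with a warning.
    """
    gene_set = {str(g).strip().upper() for g in genes}
    outside = gene_set - universe.symbols
    if outside:
        warnings.warn(
            f"{len(outside)} signature gene(s) outside the universe dropped",
            stacklevel=2,
        )
        gene_set -= outside
    n, N = len(gene_set), universe.n

    empty = pd.DataFrame(columns=list(RESULT_COLUMNS))
    if n == 0:
        warnings.warn("empty signature: enrichment is underpowered, "
                      "no tests performed", stacklevel=2)
        return empty

    rows = []
    for mirna, regulon in lib.regulons.items():
        K = len(regulon)
        overlap = sorted(regulon & gene_set)
        k = len(overlap)
        p = hypergeom_pvalue(k, K, n, N)
        rows.append(
            {
                "mirna": mirna, "k": k, "n": n, "K": K, "N": N,
                "pvalue": p,
                "ratio": enrichment_ratio(k, K, n, N),
                "overlap": ";".join(overlap),
                "small_set": (K < K_min) or (0 < k < k_min),
            }
        )
    if not rows:
        return empty
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["fdr"] < alpha
    df = df.sort_values(
        ["fdr", "k", "ratio", "mirna"], ascending=[True, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return df[list(RESULT_COLUMNS)]


def top_barplot_table(results: pd.DataFrame, top_m: int = 15) -> pd.DataFrame:
    """Bar-plot-ready top-M rows: miRNA, -log10(fdr), k, ratio."""
    head = results.head(top_m)
    return pd.DataFrame(
        {
            "mirna": head["mirna"],
            "neg_log10_fdr": -np.log10(head["fdr"].clip(lower=P_FLOOR)),
            "k": head["k"],
            "ratio": head["ratio"],
        }
    ).reset_index(drop=True)
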