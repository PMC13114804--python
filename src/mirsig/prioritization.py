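"""Categorize enriched miRNAs by disease bias and score them.

A miRNA is disease-A-biased when it is significantly enriched in at least
one A-specific direction-stratified signature and in none of disease B's;
B-biased symmetrically.  miRNAs significant in both diseases' sets, or in a
shared signature, are shared candidates (common hematologic/immune
regulation rather than disease specificity).  The composite prioritization
score integrates adjusted significance, overlap size and cross-signature
consistency:

    score = sum_s[-log10 fdr_s] + log2(1 + sum_s k_s) + c

over the signatures s where the miRNA is significant, with c the count of
such signatures.  The formula is this package's instantiation of those
three ingredients; it is deterministic, non-negative, and monotone in each
overlap count and each -log10 fdr.
"""

from __future__ import annotations

import logging
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ora import P_FLOOR

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
SHARED = "shared"

ROLE_A, ROLE_B, ROLE_SHARED = "A", "B", "shared"


def composite_score(
    evidence: Mapping[str, Tuple[float, int]], alpha: float = 0.05
) -> float:
    """Composite prioritization score from per-signature (fdr, k) evidence.

    Signatures with fdr >= alpha contribute nothing; with no significant
    signature the score is 0.
    """
    if not evidence:
        raise ConfigError("evidence map must be non-empty")
    sig = {s: (f, k) for s, (f, k) in evidence.items() if f < alpha}
    if not sig:
        return 0.0
    log_term = sum(-np.log10(max(f, P_FLOOR)) for f, _ in sig.values())
    k_total = sum(k for _, k in sig.values())
    return float(log_term + np.log2(1 + k_total) + len(sig))


def categorize_bias(
    results_by_signature: Mapping[str, pd.DataFrame],
    roles: Mapping[str, str],
    alpha: float = 0.05,
    labels: Tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Assign each tested miRNA one bias category and a composite score.

    ``results_by_signature`` maps signature name -> ranked enrichment table;
    ``roles`` maps each signature name to "A", "B" or "shared".  Category
    resolution: significant in both diseases' specific sets, or in any
    shared set, -> shared; else significant only among one disease's sets
    -> that disease's biased category; else unclassified.

    Returns a frame with one row per miRNA: category, score, best_fdr,
    n_significant and the list of signatures where it is significant.
    """
    unknown = {s for s in results_by_signature if s not in roles}
    if unknown:
        raise ConfigError(f"signatures without a role: {sorted(unknown)}")
    bad = {s: r for s, r in roles.items()
           if r not in {ROLE_A, ROLE_B, ROLE_SHARED}}
    if bad:
        raise ConfigError(f"invalid roles: {bad}")

    a_label, b_label = labels
    evidence: dict[str, dict[str, tuple[float, int]]] = {}
    for sig_name in sorted(results_by_signature):
        res = results_by_signature[sig_name]
        if res.empty:
            continue
        for row in res.itertuples(index=False):
            evidence.setdefault(row.mirna, {})[sig_name] = (
                float(row.fdr), int(row.k)
            )

    rows = []
    for mirna in sorted(evidence):
        ev = evidence[mirna]
        sig_in = sorted(s for s, (f, _) in ev.items() if f < alpha)
        roles_hit = {roles[s] for s in sig_in}
        if (ROLE_A in roles_hit and ROLE_B in roles_hit) or ROLE_SHARED in roles_hit:
            category = SHARED
        elif ROLE_A in roles_hit:
            category = f"{a_label}_biased"
        elif ROLE_B in roles_hit:
            category = f"{b_label}_biased"
        else:
            category = UNCLASSIFIED
        rows.append(
            {
                "mirna": mirna,
                "category": category,
                "score": composite_score(ev, alpha),
                "best_fdr": min(f for f, _ in ev.values()),
                "n_significant": len(sig_in),
                "significant_in": ";".join(sig_in),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna", "category", "score", "best_fdr",
                 "n_significant", "significant_in"],
    )


def shortlist(calls: pd.DataFrame, per_category_top: int = 10) -> pd.DataFrame:
    """Top-scoring miRNAs per category (ties: smaller best_fdr, then id)."""
    if per_category_top < 1:
        raise ConfigError("per_category_top must be >= 1")
    if calls.empty:
        return calls.copy()
    ranked = calls.sort_values(
        ["category", "score", "best_fdr", "mirna"],
        ascending=[True, False, True, True], kind="stable",
    )
    return (
        ranked.groupby("category", sort=True)
        .head(per_category_top)
        .reset_index(drop=True)
    )


def membership_matrix(
    results_by_signature: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """UpSet/Venn-ready boolean matrix: miRNA x signature significance."""
    cols = {}
    mirnas: set[str] = set()
    for name, res in results_by_signature.items():
        if res.empty:
            cols[name] = set()
            continue
        hits = set(res.loc[res["fdr"] < alpha, "mirna"])
        cols[name] = hits
        mirnas |= set(res["mirna"])
    index = sorted(mirnas)
    return pd.DataFrame(
        {name: [m in hits for m in index] for name, hits in sorted(cols.items())},
        index=pd.Index(index, name="mirna"),
    )
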