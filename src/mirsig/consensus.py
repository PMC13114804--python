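"""Cross-cohort consensus signatures and disease-specific partitioning.

Two consensus rules over a pair of cohorts from the same disease:

* strict intersection — a gene must be significant under the harmonized
  thresholds in *both* cohorts, with the same direction of change; suited
  to well-powered cohort pairs.
* vote-based — a gene must change in the same (nonzero) direction in both
  cohorts, meet the |log2FC| floor in both, and be FDR-significant in at
  least one; a conservative compromise when one cohort is underpowered.

Consensus signatures from two diseases are then partitioned into
disease-specific, shared-concordant and shared-discordant gene sets, and
stratified by direction for downstream enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deg_classification import DOWN, NS, UP, ThresholdConfig, classify_table
from .toptable_io import DETable

logger = logging.getLogger(__name__)

BOTH_SIGNIFICANT = "both_significant"
ONE_SIGNIFICANT = "one_significant"


@dataclass(frozen=True)
class ConsensusGene:
    """A gene surviving a cross-cohort rule, with per-cohort statistics."""

    symbol: str
    direction: str  # "up" | "down"
    stats: tuple[tuple[str, float, float], ...]  # (dataset_id, log2fc, fdr)
    support: str  # BOTH_SIGNIFICANT | ONE_SIGNIFICANT


@dataclass
class ConsensusSignature:
    """Direction-annotated gene set surviving a cross-cohort rule."""

    disease: str
    rule: str  # "strict" | "vote"
    members: dict[str, ConsensusGene] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.members)

    def direction_of(self, symbol: str) -> str:
        return self.members[symbol].direction

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.members.values():
            row = {"symbol": g.symbol, "direction": g.direction,
                   "support": g.support}
            for ds, lfc, fdr in g.stats:
                row[f"log2fc_{ds}"] = lfc
                row[f"fdr_{ds}"] = fdr
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values("symbol").reset_index(drop=True) if len(df) else df


def _merged(t1: DETable, t2: DETable) -> pd.DataFrame:
    a = t1.df[["symbol", "log2fc", "fdr"]].rename(
        columns={"log2fc": "lfc1", "fdr": "fdr1"}
    )
    b = t2.df[["symbol", "log2fc", "fdr"]].rename(
        columns={"log2fc": "lfc2", "fdr": "fdr2"}
    )
    return a.merge(b, on="symbol", how="inner")


def _build(
    t1: DETable, t2: DETable, disease: str, rule: str,
    merged: pd.DataFrame, keep: pd.Series, direction: pd.Series,
    support: pd.Series,
) -> ConsensusSignature:
    sig = ConsensusSignature(disease=disease, rule=rule)
    sel = merged.loc[keep]
    for row, d, sup in zip(sel.itertuples(index=False),
                           direction[keep], support[keep]):
        sig.members[row.symbol] = ConsensusGene(
            symbol=row.symbol,
            direction=d,
            stats=(
                (t1.dataset_id, float(row.lfc1), float(row.fdr1)),
                (t2.dataset_id, float(row.lfc2), float(row.fdr2)),
            ),
            support=sup,
        )
    return sig


def strict_intersection(
    t1: DETable, t2: DETable, thresholds: ThresholdConfig = ThresholdConfig()
) -> ConsensusSignature:
    """Genes significant in both cohorts with concordant direction."""
    merged = _merged(t1, t2)
    if merged.empty:
        logger.warning("%s/%s share no gene symbols; empty consensus",
                       t1.dataset_id, t2.dataset_id)
    c1 = classify_table(
        DETable(t1.dataset_id, t1.disease,
                merged.rename(columns={"lfc1": "log2fc", "fdr1": "fdr"})),
        thresholds)
    c2 = classify_table(
        DETable(t2.dataset_id, t2.disease,
                merged.rename(columns={"lfc2": "log2fc", "fdr2": "fdr"})),
        thresholds)
    keep = (c1 != NS) & (c1 == c2)
    support = pd.Series(BOTH_SIGNIFICANT, index=merged.index)
    return _build(t1, t2, t1.disease or t2.disease, "strict",
                  merged, keep, c1, support)


def vote_consensus(
    t1: DETable, t2: DETable, thresholds: ThresholdConfig = ThresholdConfig()
) -> ConsensusSignature:
    """Concordant nonzero direction and |log2FC| floor in both cohorts,
    FDR-significant in at least one."""
    merged = _merged(t1, t2)
    if merged.empty:
        logger.warning("%s/%s share no gene symbols; empty consensus",
                       t1.dataset_id, t2.dataset_id)
    s1, s2 = np.sign(merged["lfc1"]), np.sign(merged["lfc2"])
    concordant = (s1 == s2) & (s1 != 0)
    lfc_ok = (merged["lfc1"].abs() >= thresholds.abs_lfc_min) & (
        merged["lfc2"].abs() >= thresholds.abs_lfc_min
    )
    sig1 = merged["fdr1"] < thresholds.fdr_max
    sig2 = merged["fdr2"] < thresholds.fdr_max
    keep = concordant & lfc_ok & (sig1 | sig2)
    direction = pd.Series(np.where(s1 > 0, UP, DOWN), index=merged.index)
    support = pd.Series(
        np.where(sig1 & sig2, BOTH_SIGNIFICANT, ONE_SIGNIFICANT),
        index=merged.index,
    )
    return _build(t1, t2, t1.disease or t2.disease, "vote",
                  merged, keep, direction, support)


@dataclass
class SignaturePartition:
    """Disease-specific / shared-concordant / shared-discordant gene sets."""

    a_label: str
    b_label: str
    a_specific: dict[str, ConsensusGene] = field(default_factory=dict)
    b_specific: dict[str, ConsensusGene] = field(default_factory=dict)
    shared_concordant: dict[str, str] = field(default_factory=dict)  # sym -> dir
    shared_discordant: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def shared_symbols(self) -> frozenset[str]:
        return frozenset(self.shared_concordant) | frozenset(self.shared_discordant)

    def sizes(self) -> dict[str, int]:
        return {
            f"{self.a_label}_specific": len(self.a_specific),
            f"{self.b_label}_specific": len(self.b_specific),
            "shared_concordant": len(self.shared_concordant),
            "shared_discordant": len(self.shared_discordant),
        }


def partition_signatures(
    a: ConsensusSignature, b: ConsensusSignature
) -> SignaturePartition:
    """Set differences and intersection of two diseases' consensus sets,
    with shared genes split by direction concordance."""
    p = SignaturePartition(a_label=a.disease or "A", b_label=b.disease or "B")
    shared = a.symbols & b.symbols
    for sym in a.symbols - shared:
        p.a_specific[sym] = a.members[sym]
    for sym in b.symbols - shared:
        p.b_specific[sym] = b.members[sym]
    for sym in shared:
        da, db = a.members[sym].direction, b.members[sym].direction
        if da == db:
            p.shared_concordant[sym] = da
        else:
            p.shared_discordant[sym] = (da, db)
    return p


@dataclass(frozen=True)
class StratifiedSet:
    """A named direction-stratified gene set ready for enrichment."""

    name: str
    symbols: frozenset[str]
    directions: dict[str, str]
    role: str  # "A" | "B" | "shared"
    underpowered: bool = False

    def __len__(self) -> int:
        return len(self.symbols)


def direction_stratify(
    p: SignaturePartition, min_set_size: int = 5
) -> dict[str, StratifiedSet]:
    """Emit the six enrichment input sets.

    A-specific up/down, B-specific up/down, shared-concordant and
    shared-discordant.  Sets below ``min_set_size`` are flagged
    ``underpowered`` but still emitted.
    """

    def make(name: str, directions: dict[str, str], role: str) -> StratifiedSet:
        return StratifiedSet(
            name=name,
            symbols=frozenset(directions),
            directions=dict(directions),
            role=role,
            underpowered=len(directions) < min_set_size,
        )

    out: dict[str, StratifiedSet] = {}
    for label, members, role in (
        (p.a_label, p.a_specific, "A"),
        (p.b_label, p.b_specific, "B"),
    ):
        for direction in (UP, DOWN):
            name = f"{label}_specific_{direction}"
            dirs = {s: g.direction for s, g in members.items()
                    if g.direction == direction}
            out[name] = make(name, dirs, role)
    out["shared_concordant"] = make(
        "shared_concordant", dict(p.shared_concordant), "shared"
    )
    out["shared_discordant"] = make(
        "shared_discordant",
        {s: f"{da}|{db}" for s, (da, db) in p.shared_discordant.items()},
        "shared",
    )
    for s in out.values():
        if s.underpowered:
            logger.info("set %s has %d gene(s) (< %d): flagged underpowered",
                        s.name, len(s), min_set_size)
    return out


def write_signature(sig: ConsensusSignature, path) -> None:
    """Export a consensus signature (direction + per-cohort stats) as TSV."""
    sig.to_frame().to_csv(path, sep="\t", index=False)


def write_partition(p: SignaturePartition, path) -> None:
    """Export the partition as one tidy TSV (symbol, part, directions)."""
    rows = []
    for sym, g in sorted(p.a_specific.items()):
        rows.append((sym, f"{p.a_label}_specific", g.direction, ""))
    for sym, g in sorted(p.b_specific.items()):
        rows.append((sym, f"{p.b_label}_specific", "", g.direction))
    for sym, d in sorted(p.shared_concordant.items()):
        rows.append((sym, "shared_concordant", d, d))
    for sym, (da, db) in sorted(p.shared_discordant.items()):
        rows.append((sym, "shared_discordant", da, db))
    pd.DataFrame(
        rows,
        columns=["symbol", "part",
                 f"direction_{p.a_label}", f"direction_{p.b_label}"],
    ).to_csv(path, sep="\t", index=False)
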