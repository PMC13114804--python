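"""Bipartite miRNA–mRNA networks, degree-based hub ranking, exports.

Nodes are the retained miRNAs plus the signature genes they target; an
edge (miRNA, gene) exists when the gene lies in both the signature and the
miRNA's universe-restricted regulon (a curated validated interaction).
Hub miRNAs are ranked by degree — the number of targeted signature genes —
which stays interpretable across networks of different sizes; betweenness
is available as a secondary descriptor but never drives ranking.  Edge and
node tables are written as Cytoscape-importable TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .consensus import StratifiedSet
from .target_library import TargetLibrary

logger = logging.getLogger(__name__)

MIRNA, GENE = "miRNA", "gene"


def _signature_directions(signature) -> dict[str, str]:
    if isinstance(signature, StratifiedSet):
        return dict(signature.directions)
    if isinstance(signature, Mapping):
        return {str(s).upper(): d for s, d in signature.items()}
    return {str(s).upper(): "" for s in signature}


def build_bipartite(
    mirnas: Iterable[str] | pd.DataFrame,
    signature,
    lib: TargetLibrary,
    mirna_attrs: Mapping[str, Mapping] | None = None,
) -> nx.Graph:
    """Build the bipartite network of retained miRNAs vs signature genes.

    ``mirnas`` is an iterable of ids or an enrichment/shortlist frame with a
    ``mirna`` column (its ``fdr``/``score``/``category`` columns, when
    present, become node attributes).  miRNAs with no signature target are
    dropped with a warning; an empty edge set yields a valid empty graph.
    """
    attrs: dict[str, dict] = {m: dict(v) for m, v in (mirna_attrs or {}).items()}
    if isinstance(mirnas, pd.DataFrame):
        ids = list(mirnas["mirna"])
        for row in mirnas.itertuples(index=False):
            d = attrs.setdefault(row.mirna, {})
            for key in ("fdr", "score", "category"):
                if hasattr(row, key):
                    d.setdefault(key, getattr(row, key))
    else:
        ids = list(mirnas)

    directions = _signature_directions(signature)
    sig_set = set(directions)

    net = nx.Graph()
    n_isolated = 0
    for mirna in sorted(set(ids)):
        regulon = lib.regulons.get(mirna, frozenset())
        targets = sorted(regulon & sig_set)
        if not targets:
            n_isolated += 1
            continue
        net.add_node(mirna, node_type=MIRNA, bipartite=0, **attrs.get(mirna, {}))
        for gene in targets:
            if gene not in net:
                net.add_node(gene, node_type=GENE, bipartite=1,
                             direction=directions.get(gene, ""))
            net.add_edge(mirna, gene, interaction="targets")
    if n_isolated:
        logger.warning("%d miRNA(s) had no signature targets and were dropped",
                       n_isolated)
    if net.number_of_edges() == 0:
        logger.warning("network is empty (no miRNA–signature overlaps)")
    return net


def _nodes_of_type(net: nx.Graph, node_type: str) -> list[str]:
    return [v for v, d in net.nodes(data=True) if d.get("node_type") == node_type]


def degree_hubs(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank miRNA and gene hubs by degree.

    miRNA ties break by score (desc, when present) then id; gene hubs
    analogously by the number of regulating miRNAs.  Returns
    ``(mirna_hubs, gene_hubs)``.
    """

    def table(ids: list[str]) -> pd.DataFrame:
        rows = [
            {
                "id": v,
                "degree": net.degree(v),
                "score": net.nodes[v].get("score", float("nan")),
            }
            for v in ids
        ]
        df = pd.DataFrame(rows, columns=["id", "degree", "score"])
        if df.empty:
            return df
        df["_score"] = df["score"].fillna(float("-inf"))
        df = (
            df.sort_values(["degree", "_score", "id"],
                           ascending=[False, False, True], kind="stable")
            .drop(columns="_score")
            .reset_index(drop=True)
        )
        df.insert(1, "rank", range(1, len(df) + 1))
        return df

    return table(_nodes_of_type(net, MIRNA)), table(_nodes_of_type(net, GENE))


def betweenness_table(net: nx.Graph) -> pd.DataFrame:
    """Secondary descriptor: shortest-path betweenness per node."""
    bc = nx.betweenness_centrality(net)
    return pd.DataFrame(
        sorted(bc.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["id", "betweenness"],
    )


def export_cytoscape(
    net: nx.Graph, prefix: str | Path, top_k: int | None = None
) -> tuple[Path, Path]:
    """Write Cytoscape-importable edge and node TSV tables.

    ``top_k`` applies an export-time readability filter keeping the top-k
    miRNAs by degree (plus their targets); the in-memory network is never
    modified.  Returns (edge_path, node_path).
    """
    prefix = Path(prefix)
    sub = net
    if top_k is not None:
        mirna_hubs, _ = degree_hubs(net)
        keep = set(mirna_hubs.head(top_k)["id"])
        genes = {g for m in keep for g in net.neighbors(m)}
        sub = net.subgraph(keep | genes)

    edge_rows = [
        {"source": u if net.nodes[u].get("node_type") == MIRNA else v,
         "target": v if net.nodes[u].get("node_type") == MIRNA else u,
         "interaction": d.get("interaction", "targets")}
        for u, v, d in sub.edges(data=True)
    ]
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "interaction"])
    if len(edges):
        edges = edges.sort_values(["source", "target"]).reset_index(drop=True)

    node_rows = [
        {
            "id": v,
            "node_type": d.get("node_type", ""),
            "direction": d.get("direction", ""),
            "degree": sub.degree(v),
            "fdr": d.get("fdr", ""),
            "score": d.get("score", ""),
            "category": d.get("category", ""),
        }
        for v, d in sub.nodes(data=True)
    ]
    nodes = pd.DataFrame(
        node_rows,
        columns=["id", "node_type", "direction", "degree", "fdr", "score",
                 "category"],
    )
    if len(nodes):
        nodes = nodes.sort_values("id").reset_index(drop=True)

    edge_path = prefix.with_name(prefix.name + "_edges.tsv")
    node_path = prefix.with_name(prefix.name + "_nodes.tsv")
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)
    return edge_path, node_path


def read_cytoscape(prefix: str | Path) -> nx.Graph:
    """Reconstruct a network from exported edge/node tables (round-trip)."""
    prefix = Path(prefix)
    edges = pd.read_csv(prefix.with_name(prefix.name + "_edges.tsv"), sep="\t")
    nodes = pd.read_csv(prefix.with_name(prefix.name + "_nodes.tsv"), sep="\t")
    net = nx.Graph()
    for row in nodes.itertuples(index=False):
        attrs = {"node_type": row.node_type,
                 "bipartite": 0 if row.node_type == MIRNA else 1}
        if isinstance(row.direction, str) and row.direction:
            attrs["direction"] = row.direction
        for key in ("fdr", "score"):
            val = getattr(row, key)
            if pd.notna(val) and val != "":
                attrs[key] = float(val)
        cat = getattr(row, "category", "")
        if isinstance(cat, str) and cat:
            attrs["category"] = cat
        net.add_node(row.id, **attrs)
    for row in edges.itertuples(index=False):
        net.add_edge(row.source, row.target, interaction=row.interaction)
    return net


def write_graphml(net: nx.Graph, path: str | Path) -> Path:
    """Optional GraphML export for other graph tools."""
    path = Path(path)
    clean = nx.Graph()
    for v, d in net.nodes(data=True):
        clean.add_node(v, **{k: val for k, val in d.items() if val == val})
    clean.add_edges_from(net.edges(data=True))
    nx.write_graphml(clean, path)
    return path


def select_network_mirnas(
    results: pd.DataFrame, alpha: float = 0.05, fallback_top: int = 10
) -> pd.DataFrame:
    """Default retention: all FDR-significant miRNAs; when none pass (an
    underpowered signature), fall back to the top-ranked ``fallback_top``."""
    if results.empty:
        return results.copy()
    hits = results.loc[results["fdr"] < alpha]
    if len(hits):
        return hits.reset_index(drop=True)
    logger.info("no FDR-significant miRNA: retaining top %d by ranking",
                fallback_top)
    return results.head(fallback_top).reset_index(drop=True)
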