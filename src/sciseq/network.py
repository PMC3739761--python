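"""Network-based candidate-gene prioritization via the Relevance Index.

The systems framework: seed an interaction network with focus genes (the
top up/down-regulated genes of a contrast), optionally grow it by first
neighbors, compute each gene's connection number (undirected degree), keep
genes that are druggable or surface-accessible (plasma membrane or
extracellular space with fold change beyond the cutoff), and rank by

    RI = |log(fold change)| × connection number.

Log base defaults to 2; the ranking order is base-invariant because a base
change rescales every RI by the same positive constant — only the absolute
RI values shift.  Connection number counts distinct neighbors (multi-edges
collapse).  Genes without connections are left out of the network.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .containers import EdgeList, ValidationError, annotation_for

DRUGGABLE_LOCATIONS = frozenset({"plasma_membrane", "extracellular_space"})


def build_network(
    focus_genes,
    edges: EdgeList,
    include_neighbors: bool = False,
) -> nx.Graph:
    """Induced interaction subgraph over focus genes (plus first neighbors).

    Isolated nodes are dropped: a gene with no connection carries no network
    evidence.  Node attribute ``focus`` marks seed genes; grown-in neighbor
    nodes (the "white nodes") have ``focus=False``.
    """
    focus = set(map(str, focus_genes))
    if not focus:
        raise ValidationError("no focus genes given")
    g_full = nx.Graph()
    g_full.add_edges_from(edges.pairs())
    present = focus & set(g_full.nodes)
    if not present:
        raise ValidationError("no focus gene appears in the edge list")
    keep = set(present)
    if include_neighbors:
        for gene in present:
            keep.update(g_full.neighbors(gene))
    sub = g_full.subgraph(keep).copy()
    sub.remove_nodes_from([n for n, d in list(sub.degree()) if d == 0])
    nx.set_node_attributes(sub, {n: (n in focus) for n in sub.nodes}, "focus")
    return sub


def connection_numbers(network: nx.Graph) -> pd.Series:
    deg = pd.Series(dict(network.degree()), dtype=int, name="connection_number")
    deg.index.name = "gene"
    return deg.sort_index()


def filter_candidates(
    network: nx.Graph,
    annotations: pd.DataFrame | None,
    de_table: pd.DataFrame,
    fc_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Candidate table for network nodes with the selection-rule flag.

    A node passes when it is surface-accessible (plasma membrane or
    extracellular space) with fold change beyond ``fc_cutoff`` in either
    direction, or has drug information regardless of cellular location.
    Genes absent from the annotation default to location ``other`` without
    drug.  Nodes absent from the DE table get fold change 1 (no evidence).
    """
    nodes = sorted(network.nodes)
    ann = annotation_for(nodes, annotations)
    fc = pd.Series(1.0, index=pd.Index(nodes, name="gene"))
    known = [g for g in nodes if g in de_table.index]
    fc.loc[known] = de_table.loc[known, "fold_change"]
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "connection_number": connection_numbers(network),
            "location": ann["location"],
            "has_drug": ann["has_drug"],
        }
    )
    beyond = (table["fold_change"] > fc_cutoff) | (
        table["fold_change"] < 1.0 / fc_cutoff
    )
    surface = table["location"].isin(DRUGGABLE_LOCATIONS)
    table["passes_filter"] = (surface & beyond) | table["has_drug"]
    return table


def relevance_index(
    fold_change, connection_number, log_base: float = 2.0
):
    """RI = |log(fold change)| × connection number."""
    fc = np.asarray(fold_change, dtype=float)
    if (fc <= 0).any():
        raise ValidationError("fold change must be positive")
    deg = np.asarray(connection_number, dtype=float)
    ri = np.abs(np.log(fc) / np.log(log_base)) * deg
    return float(ri) if ri.ndim == 0 else ri


def rank_candidates(
    candidates: pd.DataFrame, log_base: float = 2.0
) -> pd.DataFrame:
    """Rank filtered candidates by descending RI.

    Ties break by higher connection number, then gene id; rank 1 is the
    largest RI.  Only rows with ``passes_filter`` are ranked.
    """
    kept = candidates[candidates["passes_filter"]].copy()
    kept["relevance_index"] = relevance_index(
        kept["fold_change"].to_numpy(), kept["connection_number"].to_numpy(), log_base
    )
    kept["_g"] = kept.index
    kept = kept.sort_values(
        ["relevance_index", "connection_number", "_g"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_g")
    kept["rank"] = np.arange(1, len(kept) + 1)
    kept.index.name = "gene"
    return kept


def prioritize(
    focus_genes,
    edges: EdgeList,
    annotations: pd.DataFrame | None,
    de_table: pd.DataFrame,
    fc_cutoff: float = 2.0,
    log_base: float = 2.0,
    include_neighbors: bool = True,
) -> pd.DataFrame:
    """Full framework: build network → filter → RI → rank."""
    network = build_network(focus_genes, edges, include_neighbors=include_neighbors)
    candidates = filter_candidates(network, annotations, de_table, fc_cutoff)
    return rank_candidates(candidates, log_base=log_base)
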