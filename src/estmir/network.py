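"""Seeded Pearson co-expression network around predicted target genes.

The graph is restricted to the 1-hop closure of the seed set: an edge
(u, v) with correlation passing the threshold is kept only when u or v is
a seed or a direct neighbour of a seed.  Node annotation (transcription
factor / kinase families) is an exact-id join against a user table.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["build_network", "annotate_nodes", "neighborhood_report"]


def build_network(
    expr: pd.DataFrame,
    seeds: set[str] | list[str],
    threshold: float = 0.7,
    mode: str = "signed",
) -> nx.Graph:
    """Correlation graph seeded by ``seeds`` over a gene-by-sample matrix.

    ``mode='signed'`` keeps edges with r >= threshold; ``mode='absolute'``
    keeps edges with |r| >= threshold.  Zero-variance genes are excluded
    from the correlation with a warning; missing seeds are kept as
    isolated nodes.  Edge weights carry the Pearson r.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    seeds = set(seeds)
    genes = list(expr.index)
    values = expr.to_numpy(dtype=float)
    variances = values.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("excluding %d zero-variance genes from correlation: %s",
                       len(dropped), dropped[:5])
    kept_genes = [g for g, k in zip(genes, keep) if k]
    graph = nx.Graph()
    for s in sorted(seeds):
        if s not in genes:
            logger.warning("seed %s absent from the expression matrix", s)
        graph.add_node(s, is_seed=True)

    if kept_genes:
        corr = np.atleast_2d(np.corrcoef(values[keep]))
        score = corr if mode == "signed" else np.abs(corr)
        index = {g: i for i, g in enumerate(kept_genes)}
        seed_idx = [index[s] for s in seeds if s in index]
        passing = score >= threshold
        np.fill_diagonal(passing, False)
        in_scope = np.zeros(len(kept_genes), dtype=bool)
        in_scope[seed_idx] = True
        if seed_idx:
            in_scope |= passing[seed_idx].any(axis=0)  # neighbours of seeds
        ii, jj = np.nonzero(np.triu(passing, k=1))
        for i, j in zip(ii, jj):
            if in_scope[i] or in_scope[j]:
                u, v = kept_genes[int(i)], kept_genes[int(j)]
                graph.add_node(u, is_seed=u in seeds)
                graph.add_node(v, is_seed=v in seeds)
                graph.add_edge(u, v, weight=float(corr[i, j]))
    for node in graph.nodes:
        graph.nodes[node].setdefault("is_seed", node in seeds)
        graph.nodes[node].setdefault("class", "other")
        graph.nodes[node].setdefault("family", "")
    return graph


def annotate_nodes(graph: nx.Graph, table: pd.DataFrame) -> nx.Graph:
    """Attach class/family attributes by exact gene-id join.

    ``table`` needs columns ``gene_id``, ``class`` (TF / kinase / other)
    and ``family``; ids absent from the table stay class ``other``.
    """
    if table is None or table.empty:
        return graph
    lookup = {
        str(row["gene_id"]): (str(row["class"]), str(row.get("family", "") or ""))
        for _, row in table.iterrows()
    }
    for node in graph.nodes:
        cls, family = lookup.get(node, ("other", ""))
        graph.nodes[node]["class"] = cls
        graph.nodes[node]["family"] = family
    return graph


def neighborhood_report(graph: nx.Graph, seeds: set[str] | list[str]) -> pd.DataFrame:
    """Per node: direct seed degree and 1/2-hop reachability from the seeds.

    Seeds themselves appear too (isolated seeds with degree 0).  Sorted by
    seed degree descending, then id ascending.
    """
    seeds = {s for s in seeds if s in graph}
    hop1: set[str] = set()
    for s in seeds:
        hop1.update(graph.neighbors(s))
    hop2 = set(hop1)
    for n in hop1:
        hop2.update(graph.neighbors(n))
    rows = []
    for node in graph.nodes:
        degree_to_seeds = sum(1 for nb in graph.neighbors(node) if nb in seeds)
        rows.append({
            "gene_id": node,
            "is_seed": node in seeds,
            "seed_degree": degree_to_seeds,
            "hop1": node in hop1,
            "hop2": node in hop2,
            "class": graph.nodes[node].get("class", "other"),
            "family": graph.nodes[node].get("family", ""),
        })
    df = pd.DataFrame(rows, columns=["gene_id", "is_seed", "seed_degree",
                                     "hop1", "hop2", "class", "family"])
    if not df.empty:
        df = df.sort_values(["seed_degree", "gene_id"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
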