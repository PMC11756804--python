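"""PPI filtering, centrality-based hub selection, and over-representation.

The PPI table is an undirected edge list with a combined-confidence score;
edges below the confidence floor (default 0.4) are discarded and the graph
is induced on the query genes (the network mRNAs).  Degree, betweenness
and closeness centralities are all computed and reported so the hub choice
is auditable; the ranking measure is configurable (degree by default).
The combined score is a filter, never an edge weight — betweenness and
closeness count unweighted shortest paths.

Over-representation uses the hypergeometric upper tail: for a query of
size n drawn from a universe of size N, a term with K members and k hits
has p = P[X >= k], X ~ Hypergeom(N, K, n), BH-adjusted across the terms
tested.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def filter_ppi_edges(
    edges: pd.DataFrame, score_min: float = 0.4
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Canonicalize and confidence-filter a PPI edge list.

    Scores on a 0-1000 scale (STRING exports) are auto-detected and
    rescaled to 0-1.  Self-loops are dropped, endpoints are ordered
    a < b, and duplicate edges keep the best score.  Returns the filtered
    table and a tally (input, self_loops, low_confidence, duplicates,
    retained).
    """
    if len(edges) == 0:
        empty = pd.DataFrame(columns=["protein_a", "protein_b", "combined_score"])
        return empty, {"input": 0, "self_loops": 0, "duplicates": 0,
                       "low_confidence": 0, "retained": 0}
    e = edges.copy()
    e["protein_a"] = e["protein_a"].astype(str).str.strip()
    e["protein_b"] = e["protein_b"].astype(str).str.strip()
    score = e["combined_score"].to_numpy(dtype=float)
    if np.nanmax(score, initial=0.0) > 1.0:
        score = score / 1000.0
    e["combined_score"] = score

    tally = {"input": len(e)}
    loops = e["protein_a"] == e["protein_b"]
    tally["self_loops"] = int(loops.sum())
    e = e[~loops]
    a = e[["protein_a", "protein_b"]].min(axis=1)
    b = e[["protein_a", "protein_b"]].max(axis=1)
    e = e.assign(protein_a=a, protein_b=b)
    n_before = len(e)
    e = e.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"].max()
    tally["duplicates"] = n_before - len(e)
    low = e["combined_score"] < score_min
    tally["low_confidence"] = int(low.sum())
    e = e[~low].reset_index(drop=True)
    tally["retained"] = len(e)
    return e, tally


def hub_genes(
    edges: pd.DataFrame,
    query_genes: set[str] | Iterable[str],
    top_n: int = 20,
    measure: str = "degree",
    score_min: float = 0.4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Rank query genes by centrality in the confidence-filtered PPI subgraph.

    All query genes become nodes (isolated ones too, which rank last with
    zero centrality everywhere).  Ties break by ascending id.  Returns the
    full ranked table — columns id, degree, betweenness, closeness, rank,
    is_hub — plus the edge-filter tally.
    """
    if measure not in ("degree", "betweenness", "closeness"):
        raise ValueError(f"unknown centrality measure {measure!r}")
    query = {str(g) for g in query_genes}
    filtered, tally = filter_ppi_edges(edges, score_min=score_min)

    g = nx.Graph()
    g.add_nodes_from(sorted(query))
    for row in filtered.itertuples(index=False):
        if row.protein_a in query and row.protein_b in query:
            g.add_edge(row.protein_a, row.protein_b)
    tally["nodes"] = g.number_of_nodes()
    tally["edges"] = g.number_of_edges()
    if g.number_of_nodes() == 0:
        warnings.warn("empty PPI graph: no query genes", stacklevel=2)
        return (
            pd.DataFrame(columns=["id", "degree", "betweenness", "closeness", "rank", "is_hub"]),
            tally,
        )

    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True)
    # closeness in the component-local convention, scaled by component reach
    clo = nx.closeness_centrality(g, wf_improved=True)
    table = pd.DataFrame(
        {
            "id": sorted(g.nodes),
            "degree": [deg[v] for v in sorted(g.nodes)],
            "betweenness": [btw[v] for v in sorted(g.nodes)],
            "closeness": [clo[v] for v in sorted(g.nodes)],
        }
    )
    table = table.sort_values(
        [measure, "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["is_hub"] = table["rank"] <= top_n
    return table, tally


def enrich(
    query: set[str] | Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: set[str] | Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene-set members are intersected with the universe; terms with no
    member in the universe are skipped.  Returns one row per tested term —
    term, k, K, n, N, pvalue, fdr — sorted by ascending p (ties by term).
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {str(g) for g in query} & universe
    n, N = len(query), len(universe)

    rows = []
    for term in sorted(gene_sets):
        members = {str(g) for g in gene_sets[term]} & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pvalue"])
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.sort_values(["pvalue", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out


def top_enriched(results: pd.DataFrame, n: int = 10, p_max: float = 0.05) -> pd.DataFrame:
    """The top-``n`` terms at raw P below ``p_max`` (report convention)."""
    return results[results["pvalue"] < p_max].head(n).reset_index(drop=True)
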