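"""Intra- and interkingdom co-occurrence networks.

Edges are Spearman correlations across samples between abundance-filtered
taxa, kept when |rho| exceeds the correlation threshold (default 0.7) and
the BH-adjusted two-sided p-value is below the significance threshold
(default 0.01); BH is applied jointly to all pairs tested for the network
being built. Topology summaries (degree, density, greedy modularity,
clustering, sign balance, per-kingdom proportions) and highest-degree
keystone taxa mirror the usual ecological-network report surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, OtuTable, ValidationError, concat_tables


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame          # source, target, rho, p_raw, p_adj, sign, interkingdom
    n_tested_pairs: int
    n_isolated_dropped: int
    skipped_taxa: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def spearman_matrix(features: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """All-pairs average-rank Spearman rho with two-sided t-approximation
    p-values; zero-variance features are skipped with a warning.

    ``features`` is taxa x samples.
    """
    if features.shape[1] < 4:
        raise ValidationError("need >= 4 samples for correlation")
    variances = features.var(axis=1)
    skipped = list(features.index[variances == 0])
    if skipped:
        warnings.warn(f"{len(skipped)} zero-variance taxa skipped",
                      RuntimeWarning, stacklevel=2)
    kept = features.loc[variances > 0]
    if kept.shape[0] < 2:
        raise ValidationError("fewer than 2 variable taxa")
    rho, p = stats.spearmanr(kept.to_numpy(), axis=1)
    if np.isscalar(rho):  # spearmanr collapses the 2-feature case
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    ids = list(kept.index)
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids), skipped)


def build_network(tables, config: AnalysisConfig | None = None,
                  apply_abundance_filter: bool = True) -> CooccurrenceNetwork:
    """Build a co-occurrence network from one table (intrakingdom) or a
    pair of tables over identical samples (interkingdom).

    Each table is abundance-filtered on its own mean relative abundances,
    tables are concatenated, Spearman correlations computed on relative
    abundances, BH applied jointly over all pairs, and edges kept iff
    p_adj < p_threshold and |rho| > r_threshold. Isolated nodes are dropped
    from the graph but counted in the provenance record.
    """
    config = config or AnalysisConfig()
    if isinstance(tables, OtuTable):
        tables = [tables]
    tables = list(tables)
    if apply_abundance_filter:
        tables = [t.filter_by_mean_abundance(config.abundance_filter)
                  for t in tables]
    table = tables[0]
    for other in tables[1:]:
        table = concat_tables(table, other)  # validates sample sets
    rel = table.relative_abundance()
    rho, p, skipped = spearman_matrix(rel)
    ids = list(rho.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    p_flat = p.to_numpy()[iu, ju]
    rho_flat = rho.to_numpy()[iu, ju]
    p_adj = multipletests(p_flat, method="fdr_bh")[1] if len(p_flat) else p_flat
    keep = (p_adj < config.p_threshold) & (np.abs(rho_flat) > config.r_threshold)
    kingdom = table.kingdom
    mean_ab = rel.mean(axis=1)
    rows = []
    for a, b, r, praw, padj in zip(np.asarray(ids)[iu][keep],
                                   np.asarray(ids)[ju][keep],
                                   rho_flat[keep], p_flat[keep], p_adj[keep]):
        rows.append({"source": a, "target": b, "rho": float(r),
                     "p_raw": float(praw), "p_adj": float(padj),
                     "sign": "positive" if r > 0 else "negative",
                     "interkingdom": kingdom[a] != kingdom[b]})
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p_raw",
                                        "p_adj", "sign", "interkingdom"])
    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["source"], e["target"], rho=e["rho"],
                   p_adj=e["p_adj"], sign=e["sign"],
                   interkingdom=bool(e["interkingdom"]))
    for node in g.nodes:
        g.nodes[node]["kingdom"] = str(kingdom[node])
        g.nodes[node]["mean_abundance"] = float(mean_ab[node])
        g.nodes[node]["lineage"] = str(table.taxonomy[node])
    n_isolated = len(ids) - g.number_of_nodes()
    return CooccurrenceNetwork(g, edges, n_tested_pairs=len(p_flat),
                               n_isolated_dropped=n_isolated,
                               skipped_taxa=skipped)


def network_topology(net: CooccurrenceNetwork) -> dict:
    """Topology summary: size, average degree 2E/N, density, greedy
    modularity Q, average clustering, sign balance and kingdom breakdown."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return {"empty": True, "n_nodes": 0, "n_edges": 0,
                "average_degree": 0.0, "density": 0.0, "modularity": 0.0,
                "clustering_coefficient": 0.0, "positive_edge_fraction": 0.0,
                "negative_edge_fraction": 0.0, "interkingdom_edges": 0,
                "node_fraction": {}, "edge_fraction": {}}
    communities = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, communities) if e else 0.0
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    pos = signs.count("positive") / e if e else 0.0
    kingdoms = nx.get_node_attributes(g, "kingdom")
    node_frac = {k: sum(1 for v in kingdoms.values() if v == k) / n
                 for k in sorted(set(kingdoms.values()))}
    edge_kinds = []
    for a, b, d in g.edges(data=True):
        if d.get("interkingdom"):
            edge_kinds.append("interkingdom")
        else:
            edge_kinds.append(kingdoms.get(a, "unknown"))
    edge_frac = {k: edge_kinds.count(k) / e for k in sorted(set(edge_kinds))} \
        if e else {}
    return {
        "empty": False,
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)) if n > 1 else 0.0,
        "modularity": float(q),
        "n_communities": len(communities),
        "clustering_coefficient": nx.average_clustering(g),
        "positive_edge_fraction": pos,
        "negative_edge_fraction": 1 - pos if e else 0.0,
        "interkingdom_edges": edge_kinds.count("interkingdom"),
        "node_fraction": node_frac,
        "edge_fraction": edge_frac,
    }


def keystone_taxa(net: CooccurrenceNetwork, k: int = 10) -> pd.DataFrame:
    """Top-k nodes by degree; ties broken by higher mean abundance, then
    lexical taxon ID."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network has no keystone taxa")
    records = [{"taxon": node, "degree": g.degree(node),
                "kingdom": g.nodes[node].get("kingdom", ""),
                "mean_abundance": g.nodes[node].get("mean_abundance", 0.0),
                "lineage": g.nodes[node].get("lineage", "")}
               for node in g.nodes]
    df = pd.DataFrame(records)
    df = df.sort_values(["degree", "mean_abundance", "taxon"],
                        ascending=[False, False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.head(min(k, len(df)))


# -- I/O ---------------------------------------------------------------------

def write_network(net: CooccurrenceNetwork, graphml_path=None,
                  edgelist_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(net.graph, str(graphml_path))
    if edgelist_path is not None:
        cols = ["source", "target", "rho", "p_adj", "sign"]
        net.edges[cols].to_csv(edgelist_path, sep="\t", index=False)


def read_network_edges(edgelist_path) -> pd.DataFrame:
    df = pd.read_csv(edgelist_path, sep="\t")
    expected = ["source", "target", "rho", "p_adj", "sign"]
    if list(df.columns) != expected:
        raise ValidationError(f"edge list columns must be {expected}")
    return df
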