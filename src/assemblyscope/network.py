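"""Co-occurrence networks: Spearman edge screening with FDR control, greedy
modularity, topology metrics, and Zi-Pi node roles.

Edges connect OTU pairs whose Spearman correlation of per-sample relative
abundances passes |rho| > rho_min with a Benjamini-Hochberg adjusted
p-value below alpha; the sign of rho is kept (positive = co-occurring,
negative = mutually exclusive). Node roles follow the within-module degree
z-score (Zi) and participation coefficient (Pi) taxonomy: peripherals,
module hubs, connectors, network hubs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OtuTable

logger = logging.getLogger(__name__)


def spearman_edge_screen(
    table: OtuTable,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    prevalence_min: int = 5,
) -> pd.DataFrame:
    """Candidate co-occurrence edges between taxa.

    Taxa present in fewer than ``prevalence_min`` samples are dropped before
    testing (rank correlations on near-constant vectors are degenerate).
    Spearman rho is computed on per-sample relative abundances for all
    remaining taxon pairs; p-values are Benjamini-Hochberg adjusted over all
    tested pairs. Kept edges satisfy |rho| > rho_min and adjusted p < alpha.
    Pairs involving a constant vector have undefined rho and are excluded
    with a logged count.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for correlation screening")
    rel = table.relative_abundance()
    prevalent = (table.counts > 0).sum(axis=1) >= prevalence_min
    rel = rel.loc[prevalent]
    taxa = list(rel.index)
    if len(taxa) < 2:
        return pd.DataFrame(
            columns=["taxon_i", "taxon_j", "rho", "p", "p_adj", "sign"]
        )
    rho, p = stats.spearmanr(rel.to_numpy().T)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu, ju = np.triu_indices(len(taxa), k=1)
    rows = pd.DataFrame(
        {
            "taxon_i": [taxa[i] for i in iu],
            "taxon_j": [taxa[j] for j in ju],
            "rho": rho[iu, ju],
            "p": p[iu, ju],
        }
    )
    defined = np.isfinite(rows["rho"]) & np.isfinite(rows["p"])
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.warning("%d taxon pairs with undefined Spearman rho excluded", n_dropped)
    rows = rows.loc[defined].reset_index(drop=True)
    if len(rows) == 0:
        rows["p_adj"] = []
        rows["sign"] = []
        return rows
    rows["p_adj"] = multipletests(rows["p"].to_numpy(), method="fdr_bh")[1]
    keep = (rows["rho"].abs() > rho_min) & (rows["p_adj"] < alpha)
    out = rows.loc[keep].reset_index(drop=True)
    out["sign"] = np.where(out["rho"] > 0, "positive", "negative")
    return out


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Graph over taxa incident to at least one kept edge (no isolates)."""
    g = nx.Graph()
    seen = set()
    for _, row in edges.iterrows():
        a, b = row["taxon_i"], row["taxon_j"]
        if a == b:
            raise ValueError(f"self-loop on taxon {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate edge {a!r}-{b!r}")
        seen.add(key)
        g.add_edge(a, b, rho=float(row["rho"]), sign=str(row.get("sign", "")))
    return g


def modularity_partition(graph: nx.Graph) -> tuple[dict, float]:
    """Greedy modularity maximization; returns node->module id and Q.

    Module ids are assigned in order of decreasing module size, ties broken
    lexicographically by smallest member, so the labelling is deterministic.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("modularity undefined for an edgeless network")
    communities = nx_community.greedy_modularity_communities(graph)
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    partition = {node: m for m, comm in enumerate(communities) for node in comm}
    q = nx_community.modularity(graph, [set(c) for c in communities])
    return partition, float(q)


def modularity_q(graph: nx.Graph, partition: dict) -> float:
    """Q = sum_m (e_m/E - (d_m/2E)^2) for a given node->module partition."""
    modules: dict = {}
    for node, m in partition.items():
        modules.setdefault(m, set()).add(node)
    return float(nx_community.modularity(graph, list(modules.values())))


def topology_metrics(graph: nx.Graph, partition: dict | None = None) -> dict:
    """Summary topology block of a co-occurrence network.

    Average path length is over connected pairs only; clustering of nodes
    with degree < 2 counts as 0; betweenness is normalized by
    (N-1)(N-2)/2 and centralization follows Freeman's formula.
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    out = {"n_vertices": n, "n_edges": e}
    if n == 0:
        out.update(
            avg_degree=math.nan, avg_clustering=math.nan,
            avg_path_length=math.nan, betweenness_centralization=math.nan,
            modularity=math.nan, n_modules=0,
        )
        return out
    out["avg_degree"] = 2.0 * e / n
    out["avg_clustering"] = float(nx.average_clustering(graph, count_zeros=True))
    total, pairs = 0, 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    out["avg_path_length"] = total / pairs if pairs else math.nan
    btw = nx.betweenness_centrality(graph, normalized=True)
    if n > 2:
        bmax = max(btw.values())
        out["betweenness_centralization"] = sum(bmax - v for v in btw.values()) / (n - 1)
    else:
        out["betweenness_centralization"] = 0.0
    if partition is not None and e > 0:
        out["modularity"] = modularity_q(graph, partition)
        out["n_modules"] = len(set(partition.values()))
    return out


def node_roles(
    graph: nx.Graph,
    partition: dict,
    zi_threshold: float = 2.5,
    pi_threshold: float = 0.62,
) -> pd.DataFrame:
    """Zi-Pi node roles.

    Zi is the z-score of a node's within-module degree among the nodes of
    its module (0 when the module's within-degree spread is 0, e.g. a
    single-node module). Pi = 1 - sum_m (k_im / k_i)^2 over modules m.
    Roles: peripheral (Zi <= zt, Pi <= pt), module_hub (Zi > zt, Pi <= pt),
    connector (Zi <= zt, Pi > pt), network_hub (both exceeded).
    """
    modules: dict = {}
    for node, m in partition.items():
        modules.setdefault(m, []).append(node)
    within = {
        node: sum(1 for nb in graph.neighbors(node) if partition[nb] == partition[node])
        for node in graph.nodes
    }
    zi = {}
    for m, members in modules.items():
        vals = np.array([within[v] for v in members], dtype=float)
        sd = vals.std(ddof=0)
        if sd == 0:
            if len(members) == 1:
                logger.warning("module %r has a single node; Zi set to 0", m)
            for v in members:
                zi[v] = 0.0
        else:
            mu = vals.mean()
            for v in members:
                zi[v] = (within[v] - mu) / sd
    rows = []
    for node in graph.nodes:
        k = graph.degree(node)
        per_mod: dict = {}
        for nb in graph.neighbors(node):
            per_mod[partition[nb]] = per_mod.get(partition[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values()) if k else 0.0
        z = zi[node]
        if z > zi_threshold and pi > pi_threshold:
            role = "network_hub"
        elif z > zi_threshold:
            role = "module_hub"
        elif pi > pi_threshold:
            role = "connector"
        else:
            role = "peripheral"
        rows.append(
            {"taxon": node, "degree": k, "module": partition[node],
             "zi": z, "pi": pi, "role": role}
        )
    return pd.DataFrame(rows)


@dataclass
class CooccurrenceNetwork:
    """A screened co-occurrence network with partition, roles and topology."""

    graph: nx.Graph
    edges: pd.DataFrame
    nodes: pd.DataFrame = field(default_factory=pd.DataFrame)
    partition: dict = field(default_factory=dict)
    topology: dict = field(default_factory=dict)


def cooccurrence_network(
    table: OtuTable,
    rho_min: float = 0.6,
    alpha: float = 0.05,
    prevalence_min: int = 5,
    zi_threshold: float = 2.5,
    pi_threshold: float = 0.62,
) -> CooccurrenceNetwork:
    """Screen edges, build the graph, partition it and annotate the nodes."""
    edges = spearman_edge_screen(table, rho_min, alpha, prevalence_min)
    graph = build_network(edges)
    if graph.number_of_edges() > 0:
        partition, _ = modularity_partition(graph)
        nodes = node_roles(graph, partition, zi_threshold, pi_threshold)
        btw = nx.betweenness_centrality(graph, normalized=True)
        nodes["betweenness"] = nodes["taxon"].map(btw)
    else:
        partition = {}
        nodes = pd.DataFrame(
            columns=["taxon", "degree", "module", "zi", "pi", "role", "betweenness"]
        )
    topology = topology_metrics(graph, partition if partition else None)
    return CooccurrenceNetwork(
        graph=graph, edges=edges, nodes=nodes, partition=partition, topology=topology
    )


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    g = net.graph.copy()
    for node in g.nodes:
        if net.partition:
            g.nodes[node]["module"] = int(net.partition[node])
    if len(net.nodes):
        roles = net.nodes.set_index("taxon")
        for node in g.nodes:
            g.nodes[node]["role"] = str(roles.loc[node, "role"])
            g.nodes[node]["zi"] = float(roles.loc[node, "zi"])
            g.nodes[node]["pi"] = float(roles.loc[node, "pi"])
    nx.write_graphml(g, path)
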