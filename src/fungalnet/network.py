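"""Signed Spearman co-occurrence networks and their topology panel.

The construction follows the standard microbial-network recipe: restrict
to the most abundant OTUs (top 400 with mean relative abundance ≥ 0.02%),
compute all pairwise Spearman correlations, and keep edges with
|ρ| > 0.6 and p < 0.05.  Edge signs record the correlation direction.
The topology panel reports node/edge counts, positive/negative edge
shares, density, average degree, connected components ("clusters"),
Freeman degree centralization, Louvain modularity, the mean modularity of
size-matched Erdős–Rényi G(n, m) graphs, and the relative modularity
(Q − Q_random)/Q_random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import OTUTable, relative_abundance


@dataclass
class CooccurrenceNetwork:
    """Undirected graph of OTU nodes with signed, ρ-weighted edges."""

    graph: nx.Graph
    rho_threshold: float = 0.6
    p_threshold: float = 0.05

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"],
             "sign": "+" if d["rho"] > 0 else "-"}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])

    def node_frame(self, partition: dict | None = None) -> pd.DataFrame:
        rows = [
            {"otu_id": n, "phylum": d.get("phylum", ""),
             "degree": self.graph.degree(n),
             "module": (partition or {}).get(n, -1)}
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows, columns=["otu_id", "phylum", "degree", "module"])


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    pct_positive_edges: float
    pct_negative_edges: float
    edge_density: float
    average_degree: float
    n_clusters: int
    centralization_degree: float
    modularity: float
    modularity_random: float
    modularity_random_sd: float
    relative_modularity: float
    module_partition: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "module_partition"}
        return d


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def select_top_otus(table: OTUTable, k: int = 400,
                    min_mean_ra: float = 0.0002) -> OTUTable:
    """Keep the ``k`` OTUs with the largest mean relative abundance, after
    dropping those below ``min_mean_ra``; boundary ties break by OTU id."""
    if k < 2:
        raise ValueError("k must be at least 2")
    mean_ra = relative_abundance(table).mean(axis=1)
    eligible = mean_ra[mean_ra >= min_mean_ra]
    if len(eligible) < 2:
        raise ValueError("fewer than two OTUs pass the abundance filter")
    order = eligible.sort_values(ascending=False, kind="stable")
    # deterministic tie-break: descending abundance, then lexicographic id
    ranked = sorted(order.index, key=lambda o: (-order[o], o))
    return table.subset_otus(ranked[:k])


def spearman_matrix(counts) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman ρ (midrank ties) with t-approximation p-values.

    Rows are OTUs, columns samples.  Constant rows get ρ = 0, p = 1 with a
    warning; |ρ| = 1 maps to p = 0.
    """
    arr = np.asarray(counts, dtype=float)
    n_otus, n_samples = arr.shape
    if n_samples < 5:
        raise ValueError("need at least 5 samples for Spearman correlations")
    if n_samples < 10:
        warnings.warn("fewer than 10 samples; correlation estimates are noisy")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant OTU rows; their "
                      "correlations are recorded as 0 with p = 1")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered ** 2).sum(axis=1))
    norm[constant] = 1.0
    normed = centered / norm[:, None]
    rho = np.clip(normed @ normed.T, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n_samples - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_samples - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)
    return rho, p


def build_network(
    rho: np.ndarray,
    p: np.ndarray,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.05,
    otu_annotations: dict | None = None,
    otu_ids: list[str] | None = None,
) -> CooccurrenceNetwork:
    """Edges where |ρ| > rho_threshold (strict) and p < p_threshold.

    Isolated OTUs are dropped from the node set, so every node has
    degree ≥ 1; an empty result warns.
    """
    rho = np.asarray(rho, dtype=float)
    p = np.asarray(p, dtype=float)
    if rho.shape != p.shape or rho.shape[0] != rho.shape[1]:
        raise ValueError("rho and p must be square matrices of equal shape")
    n = rho.shape[0]
    ids = otu_ids if otu_ids is not None else [f"OTU_{i}" for i in range(n)]
    g = nx.Graph()
    iu, ju = np.triu_indices(n, k=1)
    keep = (np.abs(rho[iu, ju]) > rho_threshold) & (p[iu, ju] < p_threshold)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], rho=float(rho[i, j]), p=float(p[i, j]),
                   sign=1 if rho[i, j] > 0 else -1)
    if g.number_of_edges() == 0:
        warnings.warn("no OTU pair passes the correlation thresholds; "
                      "the network is empty")
    if otu_annotations:
        for node in g.nodes:
            g.nodes[node]["phylum"] = otu_annotations.get(node, "")
    return CooccurrenceNetwork(g, rho_threshold, p_threshold)


def network_from_table(table: OTUTable, k: int = 400,
                       min_mean_ra: float = 0.0002,
                       rho_threshold: float = 0.6,
                       p_threshold: float = 0.05) -> CooccurrenceNetwork:
    """Abundance filter → Spearman matrix → thresholded network."""
    top = select_top_otus(table, k=k, min_mean_ra=min_mean_ra)
    rho, p = spearman_matrix(top.counts.to_numpy())
    annotations = {o: top.taxonomy[o].get("phylum") or "Unclassified"
                   for o in top.otu_ids}
    return build_network(rho, p, rho_threshold, p_threshold,
                         otu_annotations=annotations, otu_ids=top.otu_ids)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def detect_modules(net: CooccurrenceNetwork | nx.Graph, seed: int = 0,
                   restarts: int = 10) -> tuple[dict, float]:
    """Louvain modules on the unweighted, unsigned graph; best Q over
    seeded restarts.  Returns (node → module id, Q)."""
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}, 0.0
    stripped = nx.Graph()
    stripped.add_nodes_from(g.nodes)
    stripped.add_edges_from(g.edges)
    best_q, best_comms = -np.inf, None
    rng = np.random.default_rng(seed)
    for _ in range(max(restarts, 1)):
        comms = nx.community.louvain_communities(
            stripped, seed=int(rng.integers(2 ** 31)), resolution=1.0
        )
        q = nx.community.modularity(stripped, comms)
        if q > best_q:
            best_q, best_comms = q, comms
    partition = {}
    for mod_id, members in enumerate(sorted(best_comms, key=lambda c: sorted(c)[0])):
        for node in members:
            partition[node] = mod_id
    return partition, float(best_q)


def random_modularity(n_nodes: int, n_edges: int, null_reps: int = 100,
                      seed: int = 0) -> tuple[float, float]:
    """Mean ± sd Louvain modularity of Erdős–Rényi G(n, m) graphs."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    qs = []
    for _ in range(null_reps):
        g = nx.gnm_random_graph(n_nodes, n_edges,
                                seed=int(rng.integers(2 ** 31)))
        _, q = detect_modules(g, seed=int(rng.integers(2 ** 31)), restarts=1)
        qs.append(q)
    return float(np.mean(qs)), float(np.std(qs))


def relative_modularity(q_observed: float, q_random: float) -> float:
    """(Q_observed − Q_random) / Q_random; the Q/Q_random ratio is
    available as ``q_observed / q_random`` if preferred."""
    if q_random <= 0:
        raise ValueError("q_random must be positive")
    return (q_observed - q_random) / q_random


def topology(net: CooccurrenceNetwork, null_reps: int = 100,
             seed: int = 0) -> NetworkTopology:
    """The full topology panel for one network (see module docstring)."""
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    signs = np.array([d.get("sign", 1) for _, _, d in g.edges(data=True)])
    pct_pos = float((signs > 0).mean()) if m else 0.0
    degrees = np.array([d for _, d in g.degree()])
    density = m / (n * (n - 1) / 2.0) if n > 1 else 0.0
    if n > 2:
        centralization = float((degrees.max() - degrees).sum()
                               / ((n - 1.0) * (n - 2.0)))
    else:
        centralization = 0.0
    partition, q = detect_modules(net, seed=seed)
    q_rand, q_rand_sd = random_modularity(n, m, null_reps=null_reps, seed=seed)
    rel_q = relative_modularity(q, q_rand) if q_rand > 0 else float("nan")
    return NetworkTopology(
        n_nodes=n, n_edges=m,
        pct_positive_edges=pct_pos, pct_negative_edges=1.0 - pct_pos if m else 0.0,
        edge_density=float(density),
        average_degree=float(2.0 * m / n),
        n_clusters=nx.number_connected_components(g),
        centralization_degree=centralization,
        modularity=q, modularity_random=q_rand, modularity_random_sd=q_rand_sd,
        relative_modularity=float(rel_q),
        module_partition=partition,
    )


def module_similarity(
    partition_a: dict, partition_b: dict, jaccard_threshold: float = 0.3
) -> tuple[int, pd.DataFrame]:
    """Count module pairs with Jaccard overlap ≥ threshold.

    Jaccard is computed over shared OTU ids.  Each module is matched at
    most once; the count is the maximum number of one-to-one module pairs
    at or above the threshold (maximum bipartite matching, which a greedy
    descending-Jaccard pass can undercount).  Returns the count and the
    full per-pair Jaccard table.
    """
    if not partition_a or not partition_b:
        raise ValueError("partitions must be non-empty")
    mods_a: dict[int, set] = {}
    for node, mod in partition_a.items():
        mods_a.setdefault(mod, set()).add(node)
    mods_b: dict[int, set] = {}
    for node, mod in partition_b.items():
        mods_b.setdefault(mod, set()).add(node)
    rows = []
    for ma, sa in sorted(mods_a.items()):
        for mb, sb in sorted(mods_b.items()):
            union = sa | sb
            jac = len(sa & sb) / len(union) if union else 0.0
            rows.append({"module_a": ma, "module_b": mb, "jaccard": jac})
    table = pd.DataFrame(rows)
    bipartite = nx.Graph()
    left = {f"a{m}" for m in mods_a}
    bipartite.add_nodes_from(left, bipartite=0)
    bipartite.add_nodes_from((f"b{m}" for m in mods_b), bipartite=1)
    for row in table.itertuples():
        if row.jaccard >= jaccard_threshold:
            bipartite.add_edge(f"a{row.module_a}", f"b{row.module_b}")
    matching = nx.bipartite.maximum_matching(bipartite, top_nodes=left)
    count = sum(1 for k in matching if k in left)
    return count, table
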