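"""Cross-domain Spearman co-occurrence networks, modules, and keystones.

Edges connect ASV pairs whose Spearman rank correlation across samples
exceeds a positive threshold (default rho > 0.7; at n = 85 samples the
two-sided p < 0.001 critical value is about 0.355, so the threshold is far
into the significant range).  Module detection uses Louvain modularity
optimization, with label propagation and walktrap as convergence checks;
keystone candidates are the top-ranked nodes per module by betweenness
centrality and by degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.metrics import adjusted_rand_score

from edaphonet.tables import AsvTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spearman correlation and its critical value
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Tie-corrected Spearman rank correlation (Pearson on mid-ranks).

    Returns NaN when either vector has zero variance; such pairs are
    excluded from edge candidacy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def spearman_critical_value(
    n: int,
    alpha: float = 0.001,
    two_sided: bool = True,
    n_perm: int = 1_000_000,
    seed: int | None = None,
) -> dict:
    """Permutation-null critical value of |rho| for sample size ``n``.

    Monte-Carlo estimate: random permutations of the ranks 1..n are
    correlated against the identity ranking, and the (1 - alpha) quantile
    of |rho| (two-sided: P(|rho| >= c) = alpha) is returned along with the
    closed-form t-approximation c = t / sqrt(n - 2 + t^2), t the two-sided
    alpha critical value of Student's t at n - 2 degrees of freedom.
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    if n_perm < 10_000:
        log.warning(
            "spearman_critical_value: n_perm=%d gives an unstable quantile",
            n_perm,
        )
    rng = np.random.default_rng(seed)
    ident = np.arange(n, dtype=float)
    denom = n * (n**2 - 1) / 6.0
    abs_rho = np.empty(n_perm)
    batch = 200_000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.argsort(rng.random((b, n)), axis=1).astype(float)
        d2 = ((perms - ident) ** 2).sum(axis=1)
        abs_rho[done:done + b] = np.abs(1.0 - d2 / denom)
        done += b
    level = 1.0 - alpha if two_sided else 1.0 - 2.0 * alpha
    crit = float(np.quantile(abs_rho, level))
    t = sps.t.ppf(1.0 - alpha / 2.0 if two_sided else 1.0 - alpha, n - 2)
    t_approx = float(t / np.sqrt(n - 2 + t**2))
    return {"critical_value": crit, "t_approximation": t_approx,
            "n": n, "alpha": alpha, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    merged: AsvTable,
    rho_min: float = 0.7,
    taxonomy=None,
) -> tuple[nx.Graph, dict]:
    """Positive-Spearman co-occurrence network over a merged relative table.

    An edge joins ASVs i and j iff rho_ij > ``rho_min`` (positive
    correlations only); isolated nodes are dropped.  Returns the graph and
    a summary dict with node/edge counts, edges by domain pair, average
    clustering coefficient, connected components, and the average
    shortest-path length and diameter of the largest component.
    """
    if merged.n_samples < 3:
        raise ValueError("network construction needs at least 3 samples")
    x = merged.counts.to_numpy(dtype=float)
    asvs = merged.asv_ids
    variable = np.ptp(x, axis=0) > 0
    skipped = [a for a, v in zip(asvs, variable) if not v]
    if skipped:
        log.info("build_network: %d zero-variance ASV(s) excluded", len(skipped))
    idx = np.flatnonzero(variable)
    if len(idx) < 2:
        raise ValueError("fewer than 2 ASVs with variance")
    rho = sps.spearmanr(x[:, idx]).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])

    g = nx.Graph()
    ii, jj = np.triu_indices(len(idx), 1)
    strong = rho[ii, jj] > rho_min
    domain = merged.domain_of_asv
    for a, b, w in zip(ii[strong], jj[strong], rho[ii[strong], jj[strong]]):
        u, v = asvs[idx[a]], asvs[idx[b]]
        g.add_edge(u, v, weight=float(w))
    for node in g.nodes:
        g.nodes[node]["domain"] = domain[node]
        if taxonomy is not None:
            g.nodes[node]["lineage"] = taxonomy.lineage_string(node)

    summary = network_summary(g)
    summary["zero_variance_asvs"] = skipped
    summary["rho_min"] = rho_min
    return g, summary


def network_summary(g: nx.Graph) -> dict:
    pair_counts = {"bacteria-bacteria": 0, "bacteria-eukaryote": 0,
                   "eukaryote-eukaryote": 0}
    for u, v in g.edges:
        du = g.nodes[u].get("domain", "bacteria")
        dv = g.nodes[v].get("domain", "bacteria")
        key = "-".join(sorted([du, dv]))
        pair_counts[key] = pair_counts.get(key, 0) + 1
    summary = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "edges_by_domain_pair": pair_counts,
        "avg_clustering": nx.average_clustering(g) if len(g) else 0.0,
        "n_components": nx.number_connected_components(g) if len(g) else 0,
    }
    if len(g):
        giant = g.subgraph(max(nx.connected_components(g), key=len))
        summary["largest_component_size"] = giant.number_of_nodes()
        if giant.number_of_nodes() > 1:
            summary["avg_shortest_path_largest_component"] = (
                nx.average_shortest_path_length(giant)
            )
            summary["diameter_largest_component"] = nx.diameter(giant)
    return summary


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """A node -> module assignment with its modularity score.

    Module ids are dense integers starting at 1, ordered by decreasing
    module size (ties by smallest member id).
    """

    module_of_node: dict
    modularity_q: float
    algorithm: str
    seed: int | None = None
    n_modules: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_modules = len(set(self.module_of_node.values()))

    def members(self, module_id: int) -> list:
        return sorted(
            n for n, m in self.module_of_node.items() if m == module_id
        )

    def module_sizes(self) -> dict:
        sizes: dict[int, int] = {}
        for m in self.module_of_node.values():
            sizes[m] = sizes.get(m, 0) + 1
        return dict(sorted(sizes.items()))


def _densify(communities, algorithm, q, seed=None) -> ModulePartition:
    comms = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    module_of = {n: i + 1 for i, c in enumerate(comms) for n in c}
    return ModulePartition(module_of, float(q), algorithm, seed)


def modularity(g: nx.Graph, partition) -> float:
    """Newman-Girvan weighted modularity of a partition.

    Q = sum_c [ w_c / W - (s_c / 2W)^2 ] with W the total edge weight,
    w_c the intra-module weight and s_c the summed strength of module c.
    """
    module_of = getattr(partition, "module_of_node", partition)
    missing = [n for n in g.nodes if n not in module_of]
    if missing:
        raise ValueError(f"node(s) missing from partition: {missing[:5]}")
    groups: dict = {}
    for n in g.nodes:
        groups.setdefault(module_of[n], set()).add(n)
    return float(nx.community.modularity(g, groups.values(), weight="weight"))


def louvain(
    g: nx.Graph, seed: int | None = None, resolution: float = 1.0,
    restarts: int = 10,
) -> ModulePartition:
    """Louvain modularity optimization, best of ``restarts`` seeded runs."""
    if len(g) == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    best, best_q = None, -np.inf
    for _ in range(max(1, restarts)):
        s = int(rng.integers(2**31 - 1))
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=s
        )
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q:
            best, best_q = comms, q
    return _densify(best, "louvain", best_q, seed)


def label_propagation(g: nx.Graph, seed: int | None = None) -> ModulePartition:
    """Asynchronous label propagation with a seeded update order."""
    if len(g) == 0:
        raise ValueError("empty network")
    comms = list(
        nx.community.asyn_lpa_communities(g, weight="weight", seed=seed)
    )
    q = nx.community.modularity(g, comms, weight="weight")
    return _densify(comms, "label_propagation", q, seed)


def walktrap(g: nx.Graph, steps: int = 4) -> ModulePartition:
    """Short-random-walk (walktrap) agglomerative community detection.

    Uses igraph's walktrap with the merge sequence cut at maximum
    modularity; the returned Q is recomputed on the original graph.
    """
    if len(g) == 0:
        raise ValueError("empty network")
    import igraph as ig

    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g.edges[u, v].get("weight", 1.0) for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges)
    dendro = h.community_walktrap(weights=weights, steps=steps)
    clustering = dendro.as_clustering()
    comms = [{nodes[i] for i in cluster} for cluster in clustering]
    q = nx.community.modularity(g, comms, weight="weight")
    return _densify(comms, "walktrap", q)


def adjusted_rand_index(p1, p2) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    m1 = getattr(p1, "module_of_node", p1)
    m2 = getattr(p2, "module_of_node", p2)
    if set(m1) != set(m2):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(m1)
    a = [m1[n] for n in nodes]
    b = [m2[n] for n in nodes]
    return float(adjusted_rand_score(a, b))


def partition_convergence(partitions) -> pd.DataFrame:
    """Pairwise ARI among partitions (e.g. louvain/label-prop/walktrap)."""
    names = [p.algorithm for p in partitions]
    out = pd.DataFrame(np.eye(len(partitions)), index=names, columns=names)
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            ari = adjusted_rand_index(partitions[i], partitions[j])
            out.iloc[i, j] = out.iloc[j, i] = ari
    return out


# ---------------------------------------------------------------------------
# node metrics and keystone candidates
# ---------------------------------------------------------------------------

def node_metrics(g: nx.Graph, weighted_paths: bool = False) -> pd.DataFrame:
    """Degree, betweenness centrality, and local clustering per node.

    Betweenness uses Brandes accumulation over unweighted shortest paths
    (pair counts, not normalized); set ``weighted_paths=True`` to use
    1/rho edge costs instead.
    """
    if len(g) == 0:
        raise ValueError("empty network")
    if weighted_paths:
        for u, v, d in g.edges(data=True):
            d["_cost"] = 1.0 / d.get("weight", 1.0)
        btw = nx.betweenness_centrality(g, normalized=False, weight="_cost")
    else:
        btw = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree)),
            "betweenness": pd.Series(btw),
            "clustering": pd.Series(nx.clustering(g)),
        }
    ).loc[list(g.nodes)]


def keystone_candidates(
    g: nx.Graph,
    partition: ModulePartition,
    metrics: pd.DataFrame | None = None,
    top_k: int = 1,
) -> pd.DataFrame:
    """Per-module keystone-taxon candidates by betweenness and degree.

    Within each module, nodes are ranked separately by betweenness
    centrality and by degree (ties broken by the other metric, then by
    node id); the candidates are the union of the top ``top_k`` of each
    ranking, annotated with both ranks and raw values.  The node holding
    the whole network's maximum betweenness is flagged.
    """
    if metrics is None:
        metrics = node_metrics(g)
    global_max_btw = metrics["betweenness"].idxmax()
    rows = []
    for mod in sorted(set(partition.module_of_node.values())):
        members = partition.members(mod)
        sub = metrics.loc[members]
        # competition ("min") ranks: tied nodes share the better rank, so a
        # tie at the top yields multiple rank-1 candidates
        btw_rank = sub["betweenness"].rank(method="min", ascending=False)
        deg_rank = sub["degree"].rank(method="min", ascending=False)
        chosen = sorted(
            sub.index[(btw_rank <= top_k) | (deg_rank <= top_k)],
            key=lambda n: (min(btw_rank[n], deg_rank[n]), n),
        )
        for n in chosen:
            rows.append(
                {
                    "module": mod,
                    "asv": n,
                    "degree": int(metrics.loc[n, "degree"]),
                    "betweenness": float(metrics.loc[n, "betweenness"]),
                    "degree_rank": int(deg_rank[n]),
                    "betweenness_rank": int(btw_rank[n]),
                    "domain": g.nodes[n].get("domain"),
                    "lineage": g.nodes[n].get("lineage"),
                    "global_max_betweenness": n == global_max_btw,
                }
            )
    return pd.DataFrame(rows)
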