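"""Co-abundance network construction and topological characterisation.

Edges are significant SparCC correlations with |r| above a threshold
(default 0.5); the sign and magnitude of r are kept as edge attributes but
all topology metrics (clustering, modularity, shortest paths, efficiency)
are computed on the unweighted graph.  The battery covers degree
statistics, a log-log degree-distribution fit classifying networks as
random vs scale-free, Freeman degree centralization, fast-greedy module
detection, Guimerà-Amaral Zi/Pi node roles, and efficiency-based node and
network vulnerability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


def build_network(
    catalog: pd.DataFrame,
    r_min: float = 0.5,
    use_absolute: bool = True,
    abundances: dict[str, float] | pd.Series | None = None,
) -> nx.Graph:
    """Threshold an edge catalog into an undirected signed-weight graph.

    An edge is retained iff ``|r| > r_min`` (strict) in absolute mode,
    else ``r > r_min``; nodes are the OTUs incident to at least one
    retained edge.  Optional per-OTU mean relative abundances are attached
    as a node attribute.
    """
    g = nx.Graph()
    for row in catalog.itertuples(index=False):
        r = float(row.r)
        keep = (abs(r) > r_min) if use_absolute else (r > r_min)
        if not keep:
            continue
        if row.otu_a == row.otu_b:
            continue
        g.add_edge(str(row.otu_a), str(row.otu_b), r=r, weight=abs(r),
                   p=float(getattr(row, "p", np.nan)), sign=1 if r > 0 else -1)
    if g.number_of_nodes() == 0:
        warnings.warn("no edges pass the correlation threshold; network is empty")
    if abundances is not None:
        ab = pd.Series(abundances)
        for node in g.nodes:
            g.nodes[node]["abundance"] = float(ab.get(node, 0.0))
    return g


def degree_stats(network: nx.Graph) -> dict:
    """Node count, edge count, average degree (2E/N) and the degree map."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    e = network.number_of_edges()
    degrees = dict(network.degree())
    return dict(n_nodes=n, n_edges=e, average_degree=2.0 * e / n, degrees=degrees)


@dataclass
class DegreeFitResult:
    """Log-log degree-distribution fit and random/scale-free call."""

    slope: float
    r_squared: float
    classification: str
    histogram: pd.DataFrame = field(repr=False)
    cumulative: pd.DataFrame = field(repr=False)


def fit_degree_distribution(
    network: nx.Graph,
    r2_threshold: float = 0.8,
    slope_max: float = -1.0,
) -> DegreeFitResult:
    """Log-log fit of the degree distribution and a scale-free/random call.

    ``P(k)`` is the fraction of nodes with degree k.  log10 P(k) is
    regressed on log10 k over k with ``P(k) > 0``, weighting each point by
    its node count so that every node contributes equally (rare tail
    degrees, each a single node, would otherwise dominate an unweighted
    fit).  The network is called scale-free iff the fit has weighted
    R² >= ``r2_threshold`` and slope <= ``slope_max``, else random.  The
    cumulative distribution P(K >= k) is emitted alongside for visual
    judgement.
    """
    degrees = np.array([d for _, d in network.degree()])
    degrees = degrees[degrees >= 1]
    if degrees.size < 10:
        raise ValueError("need >= 10 nodes with degree >= 1")
    ks, counts = np.unique(degrees, return_counts=True)
    pk = counts / degrees.size
    hist = pd.DataFrame({"k": ks, "p_k": pk})
    cum = pd.DataFrame({"k": ks, "p_ge_k": pk[::-1].cumsum()[::-1]})
    if len(ks) < 3 or np.all(ks == ks[0]):
        # degenerate support: no power-law fit possible
        return DegreeFitResult(slope=np.nan, r_squared=0.0,
                               classification="random", histogram=hist, cumulative=cum)
    x, y, w = np.log10(ks), np.log10(pk), counts.astype(float)
    xm, ym = np.average(x, weights=w), np.average(y, weights=w)
    sxx = np.average((x - xm) ** 2, weights=w)
    syy = np.average((y - ym) ** 2, weights=w)
    sxy = np.average((x - xm) * (y - ym), weights=w)
    slope = float(sxy / sxx)
    r2 = float(sxy**2 / (sxx * syy)) if syy > 0 else 0.0
    is_sf = (r2 >= r2_threshold) and (slope <= slope_max)
    return DegreeFitResult(
        slope=slope,
        r_squared=r2,
        classification="scale_free" if is_sf else "random",
        histogram=hist,
        cumulative=cum,
    )


def detect_modules(network: nx.Graph) -> tuple[dict[str, int], int, float]:
    """Fast-greedy (CNM) modularity maximisation on the unweighted topology.

    Returns ``(node -> module id, module count, modularity)``.  Modules
    are numbered by their smallest member for a deterministic labelling;
    isolated nodes each form their own module.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    communities = nx.community.greedy_modularity_communities(network, weight=None)
    communities = sorted(communities, key=lambda c: sorted(c)[0])
    partition = {node: m for m, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(network, communities, weight=None)
    return partition, len(communities), float(q)


def global_metrics(network: nx.Graph, partition: dict[str, int] | None = None) -> dict:
    """Clustering coefficient, degree centralization, modularity, density.

    Clustering is the mean local clustering coefficient (nodes with
    degree < 2 contribute 0).  Centralization is Freeman's
    sum(k_max − k_i) / ((N−1)(N−2)); undefined (None) below 3 nodes.
    Modularity is Newman's Q of the supplied (or fast-greedy) partition
    on the unweighted topology.
    """
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    clustering = float(np.mean(list(nx.clustering(network).values())))
    if n < 3:
        warnings.warn("centralization undefined for networks with < 3 nodes")
        centralization = None
    else:
        degs = np.array([d for _, d in network.degree()], dtype=float)
        centralization = float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))
    if partition is None:
        partition, _, q = detect_modules(network)
    else:
        groups: dict[int, set] = {}
        for node, m in partition.items():
            groups.setdefault(m, set()).add(node)
        q = float(nx.community.modularity(network, list(groups.values()), weight=None))
    return dict(
        clustering_coefficient=clustering,
        centralization=centralization,
        modularity=q,
        density=float(nx.density(network)),
        n_modules=len(set(partition.values())),
    )


def zi_pi(
    network: nx.Graph,
    partition: dict[str, int],
    zi_cut: float = 2.5,
    pi_cut: float = 0.62,
) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardises a node's within-module degree against its module's
    mean and sd (0 when the sd is 0); Pi = 1 − sum_m (k_im/k_i)².  Roles
    follow the four-quadrant convention: peripheral (Zi <= zi_cut,
    Pi <= pi_cut), connector (Zi <= zi_cut, Pi > pi_cut), module hub
    (Zi > zi_cut, Pi <= pi_cut), network hub (both exceeded).  The ``hub``
    flag marks every non-peripheral node.
    """
    missing = [v for v in network.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    modules: dict[int, list] = {}
    for node in network.nodes:
        modules.setdefault(partition[node], []).append(node)

    within = {
        node: sum(1 for nb in network.neighbors(node) if partition[nb] == partition[node])
        for node in network.nodes
    }
    stats_by_module = {}
    for m, members in modules.items():
        vals = np.array([within[v] for v in members], dtype=float)
        stats_by_module[m] = (vals.mean(), vals.std(ddof=0))

    rows = []
    for node in network.nodes:
        k = network.degree(node)
        mean_w, sd_w = stats_by_module[partition[node]]
        zi = 0.0 if sd_w == 0 else (within[node] - mean_w) / sd_w
        if k == 0:
            pi = 0.0
        else:
            per_mod: dict[int, int] = {}
            for nb in network.neighbors(node):
                per_mod[partition[nb]] = per_mod.get(partition[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
        if zi > zi_cut and pi > pi_cut:
            role = "network_hub"
        elif zi > zi_cut:
            role = "module_hub"
        elif pi > pi_cut:
            role = "connector"
        else:
            role = "peripheral"
        rows.append(dict(node=node, degree=k, module=partition[node],
                         Zi=zi, Pi=pi, role=role, hub=role != "peripheral"))
    return pd.DataFrame(rows).set_index("node")


def global_efficiency(network: nx.Graph) -> float:
    """Mean inverse shortest-path length over node pairs (unweighted);
    unreachable pairs contribute 0 and a single node has efficiency 0."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("network is empty")
    if n == 1:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(network):
        for d in lengths.values():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def vulnerability(network: nx.Graph) -> dict:
    """Node vulnerability V_i = (E − E_−i)/E and its maximum.

    ``E_−i`` is the global efficiency of the induced subgraph after
    removing node i (normalised over the remaining N−1 nodes), so V_i can
    be negative when removing a peripheral node raises mean efficiency;
    such values are reported, not clamped.  The network-level
    vulnerability is the maximum over nodes.
    """
    if network.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    e_full = global_efficiency(network)
    if e_full == 0:
        raise ValueError("global efficiency is 0; vulnerability undefined")
    node_v = {}
    for node in network.nodes:
        sub = network.subgraph([v for v in network.nodes if v != node])
        node_v[node] = (e_full - global_efficiency(sub)) / e_full
    vmax_node = max(sorted(node_v), key=lambda v: node_v[v])
    return dict(
        efficiency=e_full,
        node_vulnerability=node_v,
        network_vulnerability=float(node_v[vmax_node]),
        most_vulnerable_node=vmax_node,
    )
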