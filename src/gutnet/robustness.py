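"""Network stability (wMIS, core nodes) and node-removal robustness.

A node's abundance-weighted mean interaction strength,

    wMIS_i = sum_{j in N(i)} a_j r_ij / sum_{j in N(i)} a_j,

averages its signed correlations weighted by neighbour mean relative
abundance.  Core nodes are OTUs present in the networks of all gut
locations simultaneously; the composite stability index
S = sum_{i in core} |wMIS_i| / n_total combines the three stated
ingredients (interaction strength, core-node count via the sum's support,
total node count via the normalisation) — a reconstruction, so the
components are also reported separately.

Robustness removes 50% of nodes either hub-first (targeted) or uniformly
among non-hubs (random), recomputes wMIS on the surviving subgraph, and
reports the retained fraction of total |wMIS|, replicated with a seeded
RNG.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def wmis(network: nx.Graph, abundances: dict[str, float] | pd.Series) -> pd.Series:
    """Abundance-weighted mean interaction strength per node.

    Defined for nodes with degree >= 1; a node whose neighbours all have
    zero abundance gets NaN with a warning.
    """
    ab = pd.Series(abundances, dtype=float)
    missing = [v for v in network.nodes if v not in ab.index]
    if missing:
        raise ValueError(f"abundances missing for nodes: {missing[:5]}")
    if (ab < 0).any():
        raise ValueError("abundances must be non-negative")
    out = {}
    for node in network.nodes:
        nbrs = list(network.neighbors(node))
        if not nbrs:
            continue
        weights = ab[nbrs].to_numpy()
        rs = np.array([network.edges[node, nb]["r"] for nb in nbrs])
        wsum = weights.sum()
        if wsum == 0:
            warnings.warn(f"node {node!r}: all neighbours have zero abundance; wMIS undefined")
            out[node] = np.nan
        else:
            out[node] = float((weights * rs).sum() / wsum)
    return pd.Series(out, name="wMIS")


def core_nodes(networks: dict[str, nx.Graph]) -> set[str]:
    """Nodes present in every site's network (set intersection)."""
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    sets = [set(g.nodes) for g in networks.values()]
    core = sets[0]
    for s in sets[1:]:
        core &= s
    return core


def network_stability(
    network: nx.Graph,
    abundances,
    core: set[str],
) -> dict:
    """Composite stability index S = sum_{i in core} |wMIS_i| / n_total.

    Core members absent from this network are ignored but counted in the
    report.  Also reports n_core, n_total and the mean |wMIS| over all
    nodes.
    """
    n_total = network.number_of_nodes()
    if n_total == 0:
        raise ValueError("network is empty")
    w = wmis(network, abundances)
    present = [v for v in core if v in network.nodes]
    core_w = w.reindex(present).dropna()
    s = float(core_w.abs().sum() / n_total)
    return dict(
        stability_index=s,
        n_core=len(present),
        n_core_absent=len(core) - len(present),
        n_total=n_total,
        mean_abs_wmis=float(w.abs().mean()) if len(w) else 0.0,
        wmis=w,
    )


def classify_hubs_for_removal(node_roles: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Split nodes into hub (role != peripheral) and non-hub sets."""
    hubs = set(node_roles.index[node_roles["hub"]])
    non_hubs = set(node_roles.index) - hubs
    if not hubs:
        warnings.warn("no hub nodes found; targeted removal falls back to degree ranking")
    return hubs, non_hubs


def robustness_sim(
    network: nx.Graph,
    abundances,
    strategy: str,
    hubs: set[str] | None = None,
    fraction: float = 0.5,
    replicates: int = 10,
    seed: int | None = 0,
) -> dict:
    """Node-removal robustness simulation.

    Per replicate, ``ceil(fraction * N)`` nodes are removed:

    - ``node_hub``: all hub nodes first (in random order), then
      highest-degree non-hubs until the quota is met; with no hubs the
      strategy falls back to pure highest-degree ranking.
    - ``node_random``: uniform over non-hub nodes (hubs are never removed
      unless non-hubs run out, which is flagged).

    wMIS is recomputed on the surviving induced subgraph and robustness is
    the retained fraction of total |wMIS| (nodes isolated by the removal
    contribute nothing).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if strategy not in ("node_hub", "node_random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    n = network.number_of_nodes()
    if n < 4:
        raise ValueError("need >= 4 nodes")
    hubs = set(hubs or set()) & set(network.nodes)
    non_hubs = set(network.nodes) - hubs
    base = wmis(network, abundances)
    base_total = float(base.abs().sum())
    if base_total == 0:
        raise ValueError("total |wMIS| is zero; robustness undefined")
    quota = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    degree = dict(network.degree())
    filled_from_hubs = False
    ratios = []
    for _ in range(replicates):
        if strategy == "node_hub":
            ordered = list(hubs)
            rng.shuffle(ordered)
            rest = sorted(non_hubs, key=lambda v: (-degree[v], v))
            removal = (ordered + rest)[:quota]
        else:
            pool = sorted(non_hubs)
            if len(pool) >= quota:
                removal = list(rng.choice(pool, size=quota, replace=False))
            else:
                filled_from_hubs = True
                extra = rng.choice(sorted(hubs), size=quota - len(pool), replace=False)
                removal = pool + list(extra)
        remaining = network.subgraph(set(network.nodes) - set(removal))
        w = wmis(remaining, abundances)
        ratios.append(float(w.abs().sum() / base_total))
    if filled_from_hubs:
        warnings.warn("random strategy exhausted non-hub nodes; quota filled from hubs")
    return dict(
        strategy=strategy,
        fraction=fraction,
        replicates=replicates,
        seed=seed,
        ratios=ratios,
        median_ratio=float(np.median(ratios)),
    )


def compare_robustness(
    result_a: dict,
    result_b: dict,
    additional_families: list[float] | None = None,
) -> dict:
    """Two-sided rank-sum test of two robustness replicate vectors, with
    BH correction across the supplied p-value family."""
    a = np.asarray(result_a["ratios"], dtype=float)
    b = np.asarray(result_b["ratios"], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 replicates per result")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        stat, p = np.nan, 1.0
    else:
        # exact permutation rank-sum: replicate vectors are tiny and often
        # tied, where the asymptotic Mann-Whitney approximation is poor
        def _ranksum(x, y, axis):
            ranks = stats.rankdata(np.concatenate([x, y], axis=axis), axis=axis)
            idx = np.arange(x.shape[axis])
            return np.take(ranks, idx, axis=axis).sum(axis=axis)

        res = stats.permutation_test(
            (a, b), _ranksum, permutation_type="independent",
            alternative="two-sided", vectorized=True,
            n_resamples=200_000, rng=0,
        )
        stat, p = float(res.statistic), float(res.pvalue)
    family = [p] + list(additional_families or [])
    adjusted = multipletests(family, method="fdr_bh")[1]
    return dict(
        statistic=stat,
        p_raw=p,
        p_adjusted=float(adjusted[0]),
        family_adjusted=list(map(float, adjusted)),
    )
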