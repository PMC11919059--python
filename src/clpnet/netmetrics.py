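"""Global network description and cross-network comparison.

Transitivity, average path length (APL) and the small-world index are
computed on the binarized, symmetrized, loop-free cross-lagged graph (an
edge is present wherever the selected coefficient is nonzero), the setting in
which these indices are classically defined.  Random baselines are means
over Erdos-Renyi G(n, m) graphs with the same node and edge counts, and

    small_world_index = (C / C_random) / (L / L_random).

Network comparison uses the signed-edge Jaccard index: directed edges match
only when source, target and coefficient sign all agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .estimate import SymptomNetwork


@dataclass
class GlobalMetrics:
    transitivity: float | None
    apl: float | None
    random_transitivity: float | None
    random_apl: float | None
    small_world_index: float | None
    n_random: int
    n_nodes: int
    n_edges: int
    n_unreachable_pairs: int = 0

    def to_json(self) -> dict:
        return {k: (None if v is None else (float(v) if not isinstance(v, int) else v))
                for k, v in self.__dict__.items()}


@dataclass
class ComparisonResult:
    jaccard: float
    n_shared_same_sign: int
    n_union: int


def _undirected_graph(network: SymptomNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    src, tgt = np.nonzero(network.coef)
    for i, j in zip(src, tgt):
        if i != j:
            g.add_edge(network.nodes[i], network.nodes[j])
    return g


def _apl_reachable(g: nx.Graph) -> tuple[float | None, int]:
    """Mean shortest-path length over reachable unordered pairs, plus the
    count of unreachable pairs.  None when no pair is reachable."""
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) // 2
    dist_sum = 0
    reachable = 0
    for node, dists in nx.all_pairs_shortest_path_length(g):
        for other, d in dists.items():
            if other != node:
                dist_sum += d
                reachable += 1
    reachable //= 2
    dist_sum /= 2
    if reachable == 0:
        return None, total_pairs
    return dist_sum / reachable, total_pairs - reachable


def global_metrics(network: SymptomNetwork, n_random: int = 1000,
                   seed: int = 0) -> GlobalMetrics:
    """Transitivity, APL and small-world index with random-graph baselines."""
    g = _undirected_graph(network)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 3:
        raise ValueError("global metrics need at least 3 nodes")
    if m == 0:
        return GlobalMetrics(None, None, None, None, None,
                             n_random=0, n_nodes=n, n_edges=0,
                             n_unreachable_pairs=n * (n - 1) // 2)
    trans = nx.transitivity(g)
    apl, unreachable = _apl_reachable(g)

    rng = np.random.default_rng(seed)
    r_trans = np.empty(n_random)
    r_apl = np.empty(n_random)
    for k in range(n_random):
        gr = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        r_trans[k] = nx.transitivity(gr)
        a, _ = _apl_reachable(gr)
        r_apl[k] = np.nan if a is None else a
    rand_trans = float(np.nanmean(r_trans))
    rand_apl = float(np.nanmean(r_apl))

    swi = None
    if apl is not None and rand_trans > 0 and rand_apl > 0 and apl > 0:
        swi = (trans / rand_trans) / (apl / rand_apl)
    return GlobalMetrics(transitivity=float(trans), apl=apl,
                         random_transitivity=rand_trans, random_apl=rand_apl,
                         small_world_index=swi, n_random=n_random,
                         n_nodes=n, n_edges=m, n_unreachable_pairs=unreachable)


def signed_edge_set(network: SymptomNetwork) -> set:
    """Directed cross-lagged edges as (source, target, sign) triples; the
    sign follows the OR-vs-1 convention (OR > 1 positive, OR < 1 negative)."""
    out = set()
    src, tgt = np.nonzero(network.coef)
    for i, j in zip(src, tgt):
        out.add((network.nodes[i], network.nodes[j],
                 1 if network.coef[i, j] > 0 else -1))
    return out


def jaccard_index(net_a: SymptomNetwork, net_b: SymptomNetwork) -> ComparisonResult:
    """Signed-edge Jaccard similarity of two networks on the same nodes.

    The same (source, target) pair with opposite signs in the two networks
    contributes nothing to the intersection and two elements to the union.
    Autoregressive edges are excluded by construction.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share an identical node label set")
    ea, eb = signed_edge_set(net_a), signed_edge_set(net_b)
    union = ea | eb
    shared = ea & eb
    if not union:
        return ComparisonResult(jaccard=1.0, n_shared_same_sign=0, n_union=0)
    return ComparisonResult(jaccard=len(shared) / len(union),
                            n_shared_same_sign=len(shared), n_union=len(union))
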