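"""Community detection on the mention network.

The directed multigraph is projected onto an undirected weighted graph
(parallel edges in either direction summed as the weight; self loops kept)
and partitioned by Louvain-style modularity maximization with a mandatory
seed, so a fixed seed gives a byte-identical partition. Community ids are
small integers assigned in a canonical order (by each community's smallest
member handle), independent of optimizer internals.

``n_restarts`` reruns the optimizer with derived seeds and keeps the
partition with the highest modularity — useful on small graphs where a
single Louvain pass can stop in a local optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
from networkx.algorithms import community as nx_community

from .mention_network import to_undirected_weighted


@dataclass(frozen=True)
class CommunityPartition:
    assignment: Mapping[str, int]
    modularity: float
    n_communities: int
    seed: int
    resolution: float


def detect_communities(
    network: nx.MultiDiGraph,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 1,
) -> CommunityPartition:
    """Partition the mention network by modularity maximization.

    Raises ``ValueError`` on an empty network. Modularity is computed on the
    undirected weighted projection at the given resolution.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    undirected = to_undirected_weighted(network)

    best: list[set] | None = None
    best_q = float("-inf")
    for restart in range(max(1, n_restarts)):
        communities = nx_community.louvain_communities(
            undirected, weight="weight", resolution=resolution, seed=seed + restart
        )
        if undirected.number_of_edges() == 0:
            q = 0.0
        else:
            q = nx_community.modularity(
                undirected, communities, weight="weight", resolution=resolution
            )
        if q > best_q:
            best_q, best = q, communities

    assert best is not None
    ordered = sorted(best, key=min)
    assignment = {node: cid for cid, members in enumerate(ordered) for node in members}
    return CommunityPartition(
        assignment=assignment,
        modularity=best_q,
        n_communities=len(ordered),
        seed=seed,
        resolution=resolution,
    )


@dataclass(frozen=True)
class ConnectionShares:
    """Each community's share of the network's edges, in percent of all
    directed edges, rounded to one decimal.

    ``within`` counts edges with BOTH endpoints inside the community;
    ``cross`` is the remainder. ``either`` is the alternative reading —
    edges with at least one endpoint inside — emitted for transparency
    (its values can sum past 100 because cross-community edges count
    twice).
    """

    within: Mapping[int, float]
    cross: float
    either: Mapping[int, float]
    n_edges: int


def community_connection_share(
    partition: CommunityPartition, network: nx.MultiDiGraph
) -> ConnectionShares:
    """Percent of network connections held by each community.

    Raises ``ValueError`` when the partition does not cover the network.
    """
    missing = [n for n in network.nodes if n not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    n_edges = network.number_of_edges()
    within: dict[int, int] = {cid: 0 for cid in set(partition.assignment.values())}
    either: dict[int, int] = dict(within)
    cross = 0
    for u, v in network.edges():
        cu, cv = partition.assignment[u], partition.assignment[v]
        if cu == cv:
            within[cu] += 1
            either[cu] += 1
        else:
            cross += 1
            either[cu] += 1
            either[cv] += 1

    def pct(count: int) -> float:
        return round(count / n_edges * 100, 1) if n_edges else 0.0

    return ConnectionShares(
        within={cid: pct(c) for cid, c in sorted(within.items())},
        cross=pct(cross),
        either={cid: pct(c) for cid, c in sorted(either.items())},
        n_edges=n_edges,
    )
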