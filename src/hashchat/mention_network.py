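"""Directed mention multigraph and degree summaries.

An edge is one mention: a tweet by ``source`` containing ``@target``.
Parallel edges between the same ordered pair are kept (depth analysis needs
them); a simple-graph view is a projection, never the store. Self edges
(an author mentioning their own handle) are retained and count once toward
both the out-degree and the in-degree of that node.

The node set is every tweet author plus every mentioned handle, so
participants who neither mention nor are mentioned still appear as isolated
nodes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .transcript_io import Tweet, TweetKind, classify_tweet, extract_mentions, normalize_handle

EDGE_KIND_DIRECT = "direct_mention"
EDGE_KIND_RETWEET = "retweet"
EDGE_KIND_SELF = "self"


def build_network(
    tweets: Iterable[Tweet],
    exclude: Iterable[str] = (),
) -> nx.MultiDiGraph:
    """Build the mention multigraph from a classified, window-filtered
    transcript.

    One edge per (tweet, distinct mentioned handle). Retweets generate edges
    like any other tweet: the retweeter points at every handle in the
    rendered text, including the retweeted author. Handles on ``exclude``
    are dropped both as authors and as mention targets.

    Edge attributes: ``tweet_id`` and ``kind`` (``direct_mention``,
    ``retweet`` or ``self``).
    """
    ex = {normalize_handle(h) for h in exclude}
    g = nx.MultiDiGraph()
    for tweet in tweets:
        if tweet.author in ex:
            continue
        g.add_node(tweet.author)
        is_retweet = classify_tweet(tweet) is TweetKind.RETWEET
        for target in extract_mentions(tweet.text):
            if target in ex:
                continue
            if target == tweet.author:
                kind = EDGE_KIND_SELF
            elif is_retweet:
                kind = EDGE_KIND_RETWEET
            else:
                kind = EDGE_KIND_DIRECT
            g.add_edge(tweet.author, target, tweet_id=tweet.tweet_id, kind=kind)
    return g


def degrees(network: nx.MultiDiGraph) -> pd.DataFrame:
    """Per-node degree table: handle, out_degree, in_degree, degree.

    ``degree == out_degree + in_degree``; a self edge adds one to each side
    of the same node. Sorted by total degree descending, then handle.
    """
    rows = [
        {
            "handle": node,
            "out_degree": network.out_degree(node),
            "in_degree": network.in_degree(node),
        }
        for node in network.nodes
    ]
    frame = pd.DataFrame(rows, columns=["handle", "out_degree", "in_degree"])
    frame["degree"] = frame["out_degree"] + frame["in_degree"]
    return frame.sort_values(
        ["degree", "handle"], ascending=[False, True], ignore_index=True
    )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (so -17.5 -> -18
    and 137.5 -> 138, unlike banker's rounding)."""
    from fractions import Fraction

    f = Fraction(x)
    sign = 1 if f >= 0 else -1
    a = abs(f)
    whole, rem = divmod(a.numerator, a.denominator)
    return sign * (whole + (1 if 2 * rem >= a.denominator else 0))


def network_summary(network: nx.MultiDiGraph) -> dict:
    """Whole-network counts and degree moments.

    Means and standard deviations are over all nodes; SDs are *sample*
    standard deviations (ddof=1; 0 when fewer than two nodes), a choice
    recorded in the output metadata. ``*_display`` values are the means
    rounded to the nearest integer, ties away from zero.
    """
    frame = degrees(network)
    n_nodes = int(network.number_of_nodes())
    n_edges = int(network.number_of_edges())

    def moments(col: str) -> tuple[float, float]:
        if n_nodes == 0:
            return 0.0, 0.0
        values = frame[col].to_numpy(dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if n_nodes > 1 else 0.0
        return mean, sd

    summary: dict = {"n_nodes": n_nodes, "n_edges": n_edges}
    for col in ("degree", "out_degree", "in_degree"):
        mean, sd = moments(col)
        summary[f"{col}_mean"] = mean
        summary[f"{col}_sd"] = sd
        summary[f"{col}_mean_display"] = round_half_away(mean)
        summary[f"{col}_sd_display"] = round_half_away(sd)
    summary["sd_convention"] = "sample (ddof=1)"
    return summary


def to_undirected_weighted(network: nx.MultiDiGraph) -> nx.Graph:
    """Project the directed multigraph onto an undirected weighted simple
    graph: the weight of {u, v} is the number of directed parallel edges in
    either direction; self loops are retained with their multiplicity."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for u, v in network.edges():
        a, b = (u, v) if u <= v else (v, u)
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g


def write_graphml(network: nx.MultiDiGraph, path: str) -> None:
    nx.write_graphml(network, path)


def write_gexf(network: nx.MultiDiGraph, path: str) -> None:
    nx.write_gexf(network, path)


def write_edgelist_csv(
    network: nx.MultiDiGraph, path: Union[str, IO[str]]
) -> None:
    """Edge-list CSV: source, target, tweet_id, kind — one row per edge."""
    rows = [
        {"source": u, "target": v, "tweet_id": d.get("tweet_id"), "kind": d.get("kind")}
        for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "tweet_id", "kind"]).to_csv(
        path, index=False
    )
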