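"""Engagement ratio, return on engagement (ROE), depth and breadth.

The two headline statistics of a hosted hashtag chat, both computed from a
user's mention degrees:

* **engagement ratio** — the out:in mention ratio, normalized so the smaller
  raw side is 1 and the larger side is rounded to the nearest integer
  (ties away from zero). A user with 63 outgoing and 38 incoming mentions
  has ratio 2:1; with 8 outgoing and 19 incoming, 1:2.
* **return on engagement** — ``(in - out) / out * 100``: the engagement gain
  or loss relative to the engagement invested. Undefined when the user sent
  no mentions (never reported as infinity).

Depth and breadth qualify a ratio: breadth is the number of distinct
counterparts, depth the repeat-mention multiplicity with a single
counterpart. 32 mentions to 32 distinct users and 32 mentions all to one
user can share a ratio yet describe opposite engagement styles.

All raw values are kept unrounded alongside display values so downstream
analyses never compound rounding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .mention_network import round_half_away
from .transcript_io import Tweet, normalize_handle


class UndefinedROEError(ZeroDivisionError):
    """ROE is undefined for a user with zero outgoing mentions."""


class UndefinedRatioError(ZeroDivisionError):
    """The engagement ratio is undefined when both degrees are zero."""


def roe(out_degree: int, in_degree: int) -> float:
    """Raw return on engagement, in percent: ``(in - out) / out * 100``.

    Raises :class:`UndefinedROEError` when ``out_degree`` is zero —
    undefined is distinct from an ROE of 0, which means in == out.
    """
    if out_degree == 0:
        raise UndefinedROEError("ROE undefined: no outgoing mentions")
    return (in_degree - out_degree) / out_degree * 100.0


def roe_display(out_degree: int, in_degree: int) -> int:
    """ROE rounded to the nearest whole percent, ties away from zero.

    Exact integer arithmetic, so (40, 33) -> -18 and (8, 19) -> 138 without
    binary-float drift on the .5 boundary.
    """
    if out_degree == 0:
        raise UndefinedROEError("ROE undefined: no outgoing mentions")
    return round_half_away(Fraction((in_degree - out_degree) * 100, out_degree))


@dataclass(frozen=True)
class RatioLabel:
    """Normalized out:in engagement ratio label.

    The smaller raw side is 1 and the larger carries the rounded multiple;
    when one raw count is zero that side is 0 and the other 1.
    """

    out_side: int
    in_side: int

    def __post_init__(self) -> None:
        if 0 not in (self.out_side, self.in_side) and min(self.out_side, self.in_side) != 1:
            raise ValueError(f"unnormalized ratio label {self.out_side}:{self.in_side}")

    def __str__(self) -> str:
        return f"{self.out_side}:{self.in_side}"


def engagement_ratio(out_degree: int, in_degree: int) -> RatioLabel:
    """Normalized, rounded engagement ratio for one user.

    The larger raw degree carries ``round(max/min)`` (ties away from zero,
    floor 1) and the smaller side is fixed at 1; equal degrees give 1:1.
    A zero on one side yields 0 on that side and 1 on the other. Both zero
    raises :class:`UndefinedRatioError`.
    """
    if out_degree == 0 and in_degree == 0:
        raise UndefinedRatioError("ratio undefined: no mentions either way")
    if out_degree == 0:
        return RatioLabel(0, 1)
    if in_degree == 0:
        return RatioLabel(1, 0)
    if out_degree == in_degree:
        return RatioLabel(1, 1)
    big, small = max(out_degree, in_degree), min(out_degree, in_degree)
    k = max(1, round_half_away(Fraction(big, small)))
    if out_degree > in_degree:
        return RatioLabel(k, 1)
    return RatioLabel(1, k)


@dataclass(frozen=True)
class DepthBreadth:
    """Counterpart-level view of one user's mentions.

    ``multiplicity`` maps counterpart handle -> (outgoing count, incoming
    count); a self edge makes the user its own counterpart.
    """

    breadth_out: int
    breadth_in: int
    max_depth_out: int
    max_depth_in: int
    multiplicity: Mapping[str, tuple[int, int]]


def depth_breadth(network: nx.MultiDiGraph, handle: str) -> DepthBreadth:
    """Breadth (distinct counterparts) and depth (per-counterpart
    multiplicity) for ``handle``. Raises ``KeyError`` for unknown handles."""
    handle = normalize_handle(handle)
    if handle not in network:
        raise KeyError(f"handle {handle!r} not in network")
    out_counts = Counter(v for _, v in network.out_edges(handle))
    in_counts = Counter(u for u, _ in network.in_edges(handle))
    counterparts = sorted(set(out_counts) | set(in_counts))
    return DepthBreadth(
        breadth_out=len(out_counts),
        breadth_in=len(in_counts),
        max_depth_out=max(out_counts.values(), default=0),
        max_depth_in=max(in_counts.values(), default=0),
        multiplicity={c: (out_counts.get(c, 0), in_counts.get(c, 0)) for c in counterparts},
    )


def engagement_table(
    network: nx.MultiDiGraph,
    tweets: Iterable[Tweet],
    focus: Sequence[str],
) -> pd.DataFrame:
    """Per-user engagement table for the focus handles.

    Columns mirror the standard report: tweet count from the transcript,
    out/in degrees from the network, the normalized ratio label, and ROE
    both raw and display-rounded. Users with zero outgoing mentions get a
    null ROE and ``roe_undefined=True`` rather than a number; users absent
    from both transcript and network get a row of zeros with
    ``ratio_undefined=True``.
    """
    tweet_counts = Counter(t.author for t in tweets)
    rows = []
    for raw in focus:
        h = normalize_handle(raw)
        out_d = network.out_degree(h) if h in network else 0
        in_d = network.in_degree(h) if h in network else 0
        row: dict = {
            "handle": h,
            "n_tweets": tweet_counts.get(h, 0),
            "out_degree": out_d,
            "in_degree": in_d,
            "ratio": None,
            "ratio_undefined": False,
            "roe_raw": None,
            "roe_display": None,
            "roe_undefined": False,
            "breadth_out": 0,
            "breadth_in": 0,
            "max_depth_out": 0,
        }
        try:
            row["ratio"] = str(engagement_ratio(out_d, in_d))
        except UndefinedRatioError:
            row["ratio_undefined"] = True
        try:
            row["roe_raw"] = roe(out_d, in_d)
            row["roe_display"] = roe_display(out_d, in_d)
        except UndefinedROEError:
            row["roe_undefined"] = True
        if h in network:
            db = depth_breadth(network, h)
            row["breadth_out"] = db.breadth_out
            row["breadth_in"] = db.breadth_in
            row["max_depth_out"] = db.max_depth_out
        rows.append(row)
    return pd.DataFrame(rows)
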