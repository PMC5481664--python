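"""Pipeline orchestration and report rendering.

One call runs the whole analysis on a transcript: parse, window-filter,
exclude listed handles, build the mention network, compute engagement and
community structure, optionally score supplied content coding, and write
the report bundle — participant characteristics, network summary,
engagement table, theme distribution, network exports (GraphML/GEXF/edge
list) and a run-metadata record capturing every seed and rounding rule.

Every rendered number has a raw counterpart in the machine-readable bundle;
display rounding (integer percents for participant characteristics, one
decimal for theme percents, ties away from zero) is applied only at render
time.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime
from fractions import Fraction
from typing import Optional, Sequence

import pandas as pd

from . import community_structure, content_coding, engagement_metrics, mention_network
from .mention_network import round_half_away
from .transcript_io import (
    LocationCategory,
    LocationRules,
    TranscriptSchema,
    Tweet,
    TweetKind,
    apply_exclusions,
    categorize_location,
    classify_tweet,
    filter_window,
    load_location_rules,
    parse_transcript,
)

logger = logging.getLogger("hashchat")


def participant_summary(
    tweets: Sequence[Tweet], rules: LocationRules = ()
) -> dict:
    """Participant-characteristics record: distinct authors, tweet count,
    mean (SD) tweets per participant, and location-category counts with
    whole-number display percents (ties away from zero).

    Locations are categorized per participant from the first non-blank
    profile location that participant disclosed.
    """
    authors: dict[str, Optional[str]] = {}
    for t in tweets:
        if t.author not in authors or authors[t.author] is None:
            authors[t.author] = t.profile_location
    n_participants = len(authors)
    n_tweets = len(tweets)

    if n_participants:
        counts = pd.Series([t.author for t in tweets]).value_counts()
        counts = counts.reindex(list(authors), fill_value=0)
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if n_participants > 1 else 0.0
    else:
        mean = sd = 0.0

    loc_counts = {c.value: 0 for c in LocationCategory}
    for handle, loc in authors.items():
        loc_counts[categorize_location(loc, rules).value] += 1

    def pct(count: int) -> int:
        if n_participants == 0:
            return 0
        return round_half_away(Fraction(count * 100, n_participants))

    return {
        "n_participants": n_participants,
        "n_tweets": n_tweets,
        "tweets_per_participant_mean": mean,
        "tweets_per_participant_mean_display": round_half_away(mean),
        "tweets_per_participant_sd": sd,
        "tweets_per_participant_sd_display": round_half_away(sd),
        "locations": {
            cat: {"count": cnt, "percent_display": pct(cnt)}
            for cat, cnt in loc_counts.items()
        },
    }


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; see the CLI for the file-level
    interface."""

    transcript_path: str
    out_dir: str
    schema: TranscriptSchema = field(default_factory=TranscriptSchema)
    fmt: str = "csv"
    window_start: Optional[datetime] = None
    window_end: Optional[datetime] = None
    focus: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()
    location_rules_path: Optional[str] = None
    coding_path: Optional[str] = None
    community_seed: int = 0
    community_resolution: float = 1.0


@dataclass(frozen=True)
class ReportBundle:
    """Paths of every artifact one run wrote, plus in-memory results."""

    paths: dict
    participant: dict
    network_summary: dict
    engagement: pd.DataFrame
    partition: community_structure.CommunityPartition
    themes: Optional[pd.DataFrame]


def load_coding(path: str) -> list[content_coding.CodedTweet]:
    """Read a coding file (CSV: tweet_id, coder_id, theme, subtheme)."""
    frame = pd.read_csv(path, dtype=str)
    coded = []
    for row in frame.itertuples(index=False):
        sub = getattr(row, "subtheme", None)
        if sub is not None and (pd.isna(sub) or not str(sub).strip()):
            sub = None
        coded.append(
            content_coding.CodedTweet(
                tweet_id=str(row.tweet_id),
                coder_id=str(row.coder_id),
                theme=str(row.theme),
                subtheme=sub,
            )
        )
    return coded


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``. Raises on a missing transcript or invalid window."""
    tweets = parse_transcript(config.transcript_path, config.schema, fmt=config.fmt)
    n_parsed = len(tweets)
    if config.window_start is not None and config.window_end is not None:
        tweets = filter_window(tweets, config.window_start, config.window_end)
    logger.info("window filter: %d -> %d tweets", n_parsed, len(tweets))
    if config.exclude:
        tweets = apply_exclusions(tweets, config.exclude)

    n_original = sum(1 for t in tweets if classify_tweet(t) is TweetKind.ORIGINAL)
    logger.info(
        "classification: %d original, %d retweet of %d tweets",
        n_original, len(tweets) - n_original, len(tweets),
    )

    rules: LocationRules = ()
    if config.location_rules_path:
        rules = load_location_rules(config.location_rules_path)
    participant = participant_summary(tweets, rules)

    network = mention_network.build_network(tweets, exclude=config.exclude)
    summary = mention_network.network_summary(network)

    focus = config.focus or tuple(
        mention_network.degrees(network)["handle"].head(10)
    )
    engagement = engagement_metrics.engagement_table(network, tweets, focus)

    partition = community_structure.detect_communities(
        network,
        resolution=config.community_resolution,
        seed=config.community_seed,
        n_restarts=5,
    )
    shares = community_structure.community_connection_share(partition, network)

    themes = None
    if config.coding_path:
        coded = load_coding(config.coding_path)
        reconciled = [c for c in coded if c.coder_id == "reconciled"]
        themes = content_coding.theme_distribution(reconciled or coded, tweets)
    else:
        logger.info("no coding file supplied; skipping theme distribution")

    os.makedirs(config.out_dir, exist_ok=True)
    paths = {name: os.path.join(config.out_dir, fname) for name, fname in {
        "participants": "participants.json",
        "network_summary": "network_summary.json",
        "engagement": "engagement.csv",
        "communities": "communities.csv",
        "community_shares": "community_shares.json",
        "edges": "edges.csv",
        "graphml": "network.graphml",
        "gexf": "network.gexf",
        "metadata": "run_metadata.json",
    }.items()}

    with open(paths["participants"], "w", encoding="utf-8") as fh:
        json.dump(participant, fh, indent=2)
    with open(paths["network_summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    engagement.to_csv(paths["engagement"], index=False)
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["handle", "community"]
    ).to_csv(paths["communities"], index=False)
    with open(paths["community_shares"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "within": shares.within,
                "cross": shares.cross,
                "either": shares.either,
                "n_edges": shares.n_edges,
                "modularity": partition.modularity,
                "n_communities": partition.n_communities,
            },
            fh,
            indent=2,
        )
    mention_network.write_edgelist_csv(network, paths["edges"])

    export = network.copy()
    for node, cid in partition.assignment.items():
        export.nodes[node]["community"] = cid
    deg = mention_network.degrees(network).set_index("handle")
    for node in export.nodes:
        export.nodes[node]["out_degree"] = int(deg.loc[node, "out_degree"])
        export.nodes[node]["in_degree"] = int(deg.loc[node, "in_degree"])
    mention_network.write_graphml(export, paths["graphml"])
    mention_network.write_gexf(export, paths["gexf"])

    if themes is not None:
        paths["themes"] = os.path.join(config.out_dir, "themes.csv")
        themes.to_csv(paths["themes"], index=False)

    metadata = {
        "n_tweets_parsed": n_parsed,
        "n_tweets_analyzed": len(tweets),
        "n_original": n_original,
        "n_retweet": len(tweets) - n_original,
        "window": [
            config.window_start.isoformat() if config.window_start else None,
            config.window_end.isoformat() if config.window_end else None,
        ],
        "tweet_count_scope": "tweets inside the analysis window",
        "excluded_handles": sorted(config.exclude),
        "community_seed": config.community_seed,
        "community_resolution": config.community_resolution,
        "community_projection": "undirected; parallel directed edges summed as weight; self loops kept",
        "rounding": "display values rounded half away from zero; raw values retained",
        "sd_convention": "sample (ddof=1)",
    }
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2)

    return ReportBundle(
        paths=paths,
        participant=participant,
        network_summary=summary,
        engagement=engagement,
        partition=partition,
        themes=themes,
    )
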