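"""Synthetic hosted-chat transcripts with a ground-truth ledger.

Real chat transcripts from archiving services are rarely redistributable, so
every pipeline stage here is exercised against generated transcripts whose
true per-user counts, edge list and theme labels are known exactly. The
generator emulates a one-off, hosted, hashtag-bound health chat: ~66
participants producing ~744 tweets in a 75-minute window, about a third of
them retweets, with two highly active hosts who attract a disproportionate
share of mentions and a pool of mentioned-but-silent accounts.

Defaults are the emulated chat's published headline characteristics; the
theme distribution defaults to the reconciled coding proportions of that
chat (e.g. information sharing 314/491).

Tweet text is assembled from a small template bank with real ``@mention``
tokens injected, so the parsing path (mention grammar, RT prefix) is
exercised end to end — the ledger records what the text *should* parse to,
and :func:`recover_and_compare` checks the round trip.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from fractions import Fraction
from typing import Mapping, Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np

from . import mention_network
from .transcript_io import Tweet

logger = logging.getLogger("hashchat")

#: Theme/subtheme leaves with the default (reconciled-coding) probabilities.
#: Subtheme leaves imply theme information_sharing; their probabilities sum
#: to that theme's share (314/491).
DEFAULT_THEME_PROBS: dict[tuple[str, Optional[str]], float] = {
    ("information_sharing", "health_information"): 137 / 491,
    ("information_sharing", "health_opinion"): 90 / 491,
    ("information_sharing", "health_experience"): 73 / 491,
    ("information_sharing", "asking"): 14 / 491,
    ("positive_affect_interpersonal_closeness", None): 156 / 491,
    ("action_activism_advocacy", None): 19 / 491,
    ("unable_to_determine", None): 2 / 491,
}

_BODY_TEMPLATES = (
    "A2: Social support influences every part of staying healthy",
    "so awesome! Thank you for joining the chat",
    "I walk the river levee most mornings, no gym needed",
    "new community garden opens saturday, come plant with us",
    "Q3: what keeps you motivated to stay active",
    "check out these free workout videos for beginners",
    "agreed! small daily habits beat big resolutions",
    "sign up for the weekend fun run and bring a friend",
)

_CT = ZoneInfo("America/Chicago")


@dataclass(frozen=True)
class ChatSimSpec:
    """Parameters of one simulated chat.

    ``tweets_per_participant_mean`` is the *overall* mean; host Poisson
    intensities are scaled up by ``host_activity_multiplier`` and non-host
    intensities scaled down so the expected total stays
    ``n_participants * tweets_per_participant_mean``.

    ``echo_host``/``echo_target``/``echo_prob`` force an echo chamber: each
    tweet by ``echo_host`` is, with probability ``echo_prob``, a retweet of
    an earlier ``echo_target`` tweet (when one exists), on top of the
    baseline retweet behaviour.
    """

    n_participants: int = 66
    host_handles: tuple[str, ...] = ("tulaneprc", "fitnola")
    window_start: datetime = field(default_factory=lambda: datetime(2015, 3, 5, 12, 0, tzinfo=_CT))
    window_end: datetime = field(default_factory=lambda: datetime(2015, 3, 5, 13, 15, tzinfo=_CT))
    tweets_per_participant_mean: float = 744 / 66
    retweet_prob: float = 0.34
    #: Distribution of mention counts per original tweet over {0, 1, 2, 3}.
    mention_count_distribution: tuple[float, float, float, float] = (0.75, 0.22, 0.02, 0.01)
    host_attraction: float = 14.0
    host_activity_multiplier: float = 6.0
    theme_probs: Mapping[tuple[str, Optional[str]], float] = field(
        default_factory=lambda: dict(DEFAULT_THEME_PROBS)
    )
    self_mention_prob: float = 0.01
    n_bystander_handles: int = 69
    #: (target_city, other_us, unavailable) profile-location probabilities.
    location_probs: tuple[float, float, float] = (39 / 66, 15 / 66, 12 / 66)
    hashtag: str = "#livefitnola"
    echo_host: Optional[str] = None
    echo_target: Optional[str] = None
    echo_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < len(self.host_handles):
            raise ValueError("fewer participants than hosts")
        if not self.window_start < self.window_end:
            raise ValueError("window start must precede end")
        for p in (self.retweet_prob, self.self_mention_prob, self.echo_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of range: {p}")
        if abs(sum(self.mention_count_distribution) - 1) > 1e-9:
            raise ValueError("mention_count_distribution must sum to 1")
        if abs(sum(self.theme_probs.values()) - 1) > 1e-9:
            raise ValueError("theme_probs must sum to 1")
        if self.host_attraction < 1:
            raise ValueError("host_attraction must be >= 1")


@dataclass
class GroundTruthLedger:
    """Exact per-user and per-tweet truth for one simulated transcript."""

    tweet_counts: Counter
    out_counts: Counter
    in_counts: Counter
    #: (source, target, tweet_id, kind) per edge, in emission order.
    edges: list[tuple[str, str, str, str]]
    #: tweet_id -> (theme, subtheme) for original tweets.
    themes: dict[str, tuple[str, Optional[str]]]
    n_retweet_fallbacks: int = 0

    def edges_by_tweet(self) -> dict[str, frozenset[tuple[str, str]]]:
        by_tweet: dict[str, set[tuple[str, str]]] = {}
        for source, target, tweet_id, _ in self.edges:
            by_tweet.setdefault(tweet_id, set()).add((source, target))
        return {tid: frozenset(pairs) for tid, pairs in by_tweet.items()}


@dataclass
class _Draft:
    author: str
    text: str
    mentions: tuple[str, ...]  # distinct, textual order


def simulate_chat(spec: ChatSimSpec) -> tuple[list[Tweet], GroundTruthLedger]:
    """Generate one chat transcript plus its ground-truth ledger.

    Fully reproducible from ``spec.seed``. Per participant the tweet count
    is Poisson; timestamps are uniform in the window; each tweet is, with
    probability ``retweet_prob``, a rendered ``RT @author: ...`` of a
    uniformly chosen earlier tweet (falling back to an original, logged,
    when none exists yet), otherwise an original whose mention targets are
    drawn without replacement with hosts upweighted by ``host_attraction``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    hosts = tuple(h.lower() for h in spec.host_handles)
    n_plain = spec.n_participants - len(hosts)
    participants = list(hosts) + [f"user{i:03d}" for i in range(1, n_plain + 1)]
    bystanders = [f"guest{i:03d}" for i in range(1, spec.n_bystander_handles + 1)]
    pool = np.array(participants + bystanders)
    weights = np.array(
        [spec.host_attraction if h in hosts else 1.0 for h in pool], dtype=float
    )

    # Scale intensities so hosts tweet more while the expected total stays
    # n_participants * tweets_per_participant_mean.
    mult = spec.host_activity_multiplier
    denom = n_plain + mult * len(hosts)
    base = spec.tweets_per_participant_mean * spec.n_participants / denom
    intensities = [base * (mult if h in hosts else 1.0) for h in participants]

    loc_strings = ("New Orleans, LA", "Houston, TX", None)
    locations = {
        h: loc_strings[rng.choice(3, p=spec.location_probs)] for h in participants
    }

    duration = (spec.window_end - spec.window_start).total_seconds()
    events: list[tuple[float, str]] = []
    for handle, lam in zip(participants, intensities):
        for _ in range(rng.poisson(lam)):
            events.append((float(rng.uniform(0, duration)), handle))
    events.sort(key=lambda e: e[0])

    theme_leaves = list(spec.theme_probs.keys())
    theme_p = np.array([spec.theme_probs[k] for k in theme_leaves], dtype=float)
    theme_p = theme_p / theme_p.sum()
    mention_p = np.array(spec.mention_count_distribution, dtype=float)

    tweets: list[Tweet] = []
    drafts: list[_Draft] = []
    ledger = GroundTruthLedger(
        tweet_counts=Counter(),
        out_counts=Counter(),
        in_counts=Counter(),
        edges=[],
        themes={},
    )

    for i, (offset, author) in enumerate(events):
        tweet_id = f"s{i + 1:06d}"
        created = spec.window_start + timedelta(seconds=offset)

        wants_echo = (
            author == spec.echo_host
            and spec.echo_prob > 0
            and rng.random() < spec.echo_prob
        )
        echo_sources = (
            [d for d in drafts if d.author == spec.echo_target] if wants_echo else []
        )
        wants_retweet = wants_echo or rng.random() < spec.retweet_prob

        if wants_echo and echo_sources:
            src = echo_sources[int(rng.integers(len(echo_sources)))]
            draft = _render_retweet(author, src)
            is_retweet = True
        elif wants_retweet and drafts and not wants_echo:
            src = drafts[int(rng.integers(len(drafts)))]
            draft = _render_retweet(author, src)
            is_retweet = True
        else:
            if wants_retweet:
                ledger.n_retweet_fallbacks += 1
                logger.debug("retweet requested before any source exists; emitting original")
            draft = _render_original(
                author, rng, pool, weights, mention_p, spec
            )
            is_retweet = False
            leaf = theme_leaves[int(rng.choice(len(theme_leaves), p=theme_p))]
            ledger.themes[tweet_id] = leaf

        tweets.append(
            Tweet(
                tweet_id=tweet_id,
                author=author,
                text=draft.text,
                created_at=created,
                profile_location=locations.get(author),
            )
        )
        drafts.append(draft)

        ledger.tweet_counts[author] += 1
        for target in draft.mentions:
            if target == author:
                kind = mention_network.EDGE_KIND_SELF
            elif is_retweet:
                kind = mention_network.EDGE_KIND_RETWEET
            else:
                kind = mention_network.EDGE_KIND_DIRECT
            ledger.edges.append((author, target, tweet_id, kind))
            ledger.out_counts[author] += 1
            ledger.in_counts[target] += 1

    return tweets, ledger


def _render_retweet(author: str, src: _Draft) -> _Draft:
    text = f"RT @{src.author}: {src.text}"
    mentions: list[str] = [src.author]
    for m in src.mentions:
        if m not in mentions:
            mentions.append(m)
    return _Draft(author=author, text=text, mentions=tuple(mentions))


def _render_original(
    author: str,
    rng: np.random.Generator,
    pool: np.ndarray,
    weights: np.ndarray,
    mention_p: np.ndarray,
    spec: ChatSimSpec,
) -> _Draft:
    n_mentions = int(rng.choice(4, p=mention_p))
    others_mask = pool != author
    candidates = pool[others_mask]
    w = weights[others_mask]
    n_mentions = min(n_mentions, len(candidates))
    if n_mentions:
        picked = rng.choice(
            candidates, size=n_mentions, replace=False, p=w / w.sum()
        )
        mentions = [str(m) for m in picked]
    else:
        mentions = []
    if rng.random() < spec.self_mention_prob:
        mentions.append(author)
    body = _BODY_TEMPLATES[int(rng.integers(len(_BODY_TEMPLATES)))]
    prefix = "".join(f"@{m} " for m in mentions)
    text = f"{prefix}{body} {spec.hashtag}"
    return _Draft(author=author, text=text, mentions=tuple(mentions))


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of checking pipeline-computed degrees against the ledger."""

    n_tweets: int
    degree_mismatches: Mapping[str, tuple[tuple[int, int], tuple[int, int]]]
    mismatched_tweet_ids: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.degree_mismatches and not self.mismatched_tweet_ids


def recover_and_compare(
    transcript: Sequence[Tweet], ledger: GroundTruthLedger
) -> ComparisonReport:
    """Rebuild the mention network from the transcript text and compare
    per-user out/in degrees — and per-tweet edge sets — with the ledger.

    A clean round trip reports no mismatches; any divergence lists the
    offending handles and tweet_ids.
    """
    network = mention_network.build_network(transcript)

    degree_mismatches: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    handles = set(ledger.out_counts) | set(ledger.in_counts) | set(network.nodes)
    for h in sorted(handles):
        truth = (ledger.out_counts.get(h, 0), ledger.in_counts.get(h, 0))
        got = (
            network.out_degree(h) if h in network else 0,
            network.in_degree(h) if h in network else 0,
        )
        if truth != got:
            degree_mismatches[h] = (truth, got)

    truth_by_tweet = ledger.edges_by_tweet()
    got_by_tweet: dict[str, set[tuple[str, str]]] = {}
    for u, v, data in network.edges(data=True):
        got_by_tweet.setdefault(data["tweet_id"], set()).add((u, v))
    bad_ids = sorted(
        tid
        for tid in set(truth_by_tweet) | set(got_by_tweet)
        if truth_by_tweet.get(tid, frozenset()) != frozenset(got_by_tweet.get(tid, set()))
    )

    return ComparisonReport(
        n_tweets=len(transcript),
        degree_mismatches=degree_mismatches,
        mismatched_tweet_ids=tuple(bad_ids),
    )
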