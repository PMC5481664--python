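"""Read, validate and annotate hashtag-chat transcripts.

A transcript is an ordered collection of tweets exported from an archiving
service as delimited text (CSV/TSV with a header) or as one JSON record per
line. This module normalizes author handles, extracts ``@username`` mentions
from tweet text, classifies tweets as originals or retweets, restricts the
record to the timed chat window, and maps self-disclosed profile locations to
coarse categories.

Handles are stored lowercase and without the ``@`` prefix; the platform
username grammar is 1-15 word characters (letters, digits, underscore).
"""

from __future__ import annotations

import enum
import io
import logging
import re
import string
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import IO, Iterable, Mapping, Optional, Sequence, Union
from zoneinfo import ZoneInfo

import pandas as pd
import yaml

logger = logging.getLogger("hashchat")

#: Username grammar: 1-15 word characters.
HANDLE_RE = re.compile(r"\w{1,15}\Z", re.ASCII)

#: A mention is "@" + username, where the "@" is at start-of-string or
#: preceded by a non-word character, and the username token is maximal
#: (a 16-word-character token is not a valid mention at all).
MENTION_RE = re.compile(r"(?<!\w)@(\w{1,15})(?!\w)", re.ASCII)

#: "RT @someone" prefix (optionally after whitespace), case-insensitive on RT.
RT_PREFIX_RE = re.compile(r"\s*RT\s+@\w{1,15}", re.IGNORECASE | re.ASCII)


class TranscriptError(ValueError):
    """Unresolvable schema or malformed transcript input."""


def normalize_handle(raw: str) -> str:
    """Canonical lowercase handle: strip whitespace, a leading ``@`` and
    trailing punctuation. Idempotent: ``@TulanePRC``, ``tulaneprc`` and
    ``@tulaneprc`` all map to ``tulaneprc``.

    Raises ``ValueError`` if the remainder does not match the username
    grammar.
    """
    h = raw.strip()
    if h.startswith("@"):
        h = h[1:]
    h = h.rstrip(string.punctuation + string.whitespace)
    h = h.lower()
    if not HANDLE_RE.match(h):
        raise ValueError(f"not a valid handle: {raw!r}")
    return h


class TweetKind(enum.Enum):
    ORIGINAL = "original"
    RETWEET = "retweet"


class LocationCategory(enum.Enum):
    TARGET_CITY = "target_city"
    OTHER_US = "other_us"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class Tweet:
    """One transcript record.

    ``created_at`` must be timezone-aware: chat windows are stated in a
    named local timezone and naive stamps are ambiguous.
    """

    tweet_id: str
    author: str
    text: str
    created_at: datetime
    profile_location: Optional[str] = None
    retweet_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.created_at.tzinfo is None:
            raise ValueError(f"tweet {self.tweet_id}: naive timestamp")


@dataclass(frozen=True)
class TranscriptSchema:
    """Column mapping from a source file onto :class:`Tweet` fields.

    ``author``, ``text`` and ``created_at`` are required column names;
    the rest are optional. ``timezone`` is the transcript's declared zone:
    naive timestamps are localized to it, aware ones converted to it.
    """

    author: str = "author"
    text: str = "text"
    created_at: str = "created_at"
    tweet_id: Optional[str] = "tweet_id"
    retweet_flag: Optional[str] = None
    profile_location: Optional[str] = "profile_location"
    timezone: str = "America/Chicago"
    max_text_length: Optional[int] = None


_TRUTHY = {"true", "1", "yes", "y", "t", "rt"}


def _as_flag(value: object) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    if isinstance(value, (int,)):
        return bool(value)
    s = str(value).strip().lower()
    if not s:
        return None
    return s in _TRUTHY


def parse_transcript(
    source: Union[str, IO[str]],
    schema: TranscriptSchema = TranscriptSchema(),
    fmt: str = "csv",
) -> list[Tweet]:
    """Read a transcript into an ordered list of :class:`Tweet`.

    ``fmt`` is ``"csv"``, ``"tsv"`` or ``"jsonl"``. Rows missing the author
    or the text are dropped; the drop count is reported at INFO level.
    Authors are normalized handles; rows whose author cannot be normalized
    are dropped too (they cannot participate in a mention network).

    Raises :class:`TranscriptError` when the schema's required columns are
    absent, and lets I/O errors from an unreadable source propagate.
    """
    if fmt == "csv":
        frame = pd.read_csv(source, dtype=str)
    elif fmt == "tsv":
        frame = pd.read_csv(source, sep="\t", dtype=str)
    elif fmt == "jsonl":
        frame = pd.read_json(source, lines=True, dtype=str, convert_dates=False)
    else:
        raise TranscriptError(f"unknown transcript format: {fmt!r}")

    required = [schema.author, schema.text, schema.created_at]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TranscriptError(
            f"transcript lacks required columns {missing}; found {list(frame.columns)}"
        )

    tz = ZoneInfo(schema.timezone)
    tweets: list[Tweet] = []
    dropped = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        record = dict(zip(frame.columns, row))
        raw_author = record.get(schema.author)
        raw_text = record.get(schema.text)
        if _blank(raw_author) or _blank(raw_text):
            dropped += 1
            continue
        try:
            author = normalize_handle(str(raw_author))
        except ValueError:
            dropped += 1
            continue

        stamp = pd.Timestamp(str(record[schema.created_at]))
        if stamp.tzinfo is None:
            stamp = stamp.tz_localize(tz)
        else:
            stamp = stamp.tz_convert(tz)

        text = str(raw_text)
        if schema.max_text_length is not None and len(text) > schema.max_text_length:
            logger.info("truncating tweet text at %d chars", schema.max_text_length)
            text = text[: schema.max_text_length]

        tweet_id = (
            str(record[schema.tweet_id])
            if schema.tweet_id and not _blank(record.get(schema.tweet_id))
            else f"t{i + 1:06d}"
        )
        flag = _as_flag(record.get(schema.retweet_flag)) if schema.retweet_flag else None
        loc = record.get(schema.profile_location) if schema.profile_location else None
        loc = None if _blank(loc) else str(loc)

        tweets.append(
            Tweet(
                tweet_id=tweet_id,
                author=author,
                text=text,
                created_at=stamp.to_pydatetime(),
                profile_location=loc,
                retweet_flag=flag,
            )
        )

    logger.info(
        "parsed %d tweets (%d rows dropped for missing/invalid author or text)",
        len(tweets),
        dropped,
    )
    _check_unique_ids(tweets)
    return tweets


def _blank(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and pd.isna(value):
        return True
    return not str(value).strip()


def _check_unique_ids(tweets: Sequence[Tweet]) -> None:
    seen: set[str] = set()
    for t in tweets:
        if t.tweet_id in seen:
            raise TranscriptError(f"duplicate tweet_id {t.tweet_id!r}")
        seen.add(t.tweet_id)


def extract_mentions(text: str) -> list[str]:
    """All distinct mentioned handles in ``text``, in order of first
    occurrence, lowercased.

    A mention is a maximal ``@username`` token whose ``@`` is preceded by
    start-of-string or a non-word character, so ``info@example.com`` yields
    nothing. Repeated mentions of the same handle collapse to one entry.
    """
    out: list[str] = []
    seen: set[str] = set()
    for m in MENTION_RE.finditer(text):
        h = m.group(1).lower()
        if h not in seen:
            seen.add(h)
            out.append(h)
    return out


def classify_tweet(tweet: Tweet) -> TweetKind:
    """Retweet iff the source-provided flag is true, or the text starts with
    the conventional ``RT @handle`` marker; otherwise original."""
    if tweet.retweet_flag:
        return TweetKind.RETWEET
    if RT_PREFIX_RE.match(tweet.text):
        return TweetKind.RETWEET
    return TweetKind.ORIGINAL


def filter_window(
    tweets: Iterable[Tweet], start: datetime, end: datetime
) -> list[Tweet]:
    """Tweets with ``start <= created_at < end`` (half-open), input order
    preserved. Both bounds must be timezone-aware and ``start < end``."""
    if start.tzinfo is None or end.tzinfo is None:
        raise ValueError("window bounds must be timezone-aware")
    if not start < end:
        raise ValueError("window start must precede end")
    return [t for t in tweets if start <= t.created_at < end]


def apply_exclusions(
    tweets: Iterable[Tweet], excluded: Iterable[str]
) -> list[Tweet]:
    """Drop tweets authored by any handle on the exclusion list (e.g. known
    bots). Handles are normalized before comparison; mention *targets* on the
    list are removed at network-build time."""
    ex = {normalize_handle(h) for h in excluded}
    tweets = list(tweets)
    kept = [t for t in tweets if t.author not in ex]
    logger.info(
        "exclusion filter: %d of %d tweets kept", len(kept), len(tweets)
    )
    return kept


LocationRules = Sequence[tuple[str, LocationCategory]]


def categorize_location(
    profile_location: Optional[str], rules: LocationRules
) -> LocationCategory:
    """Map a self-disclosed free-text location to a category.

    Blank or missing locations are ``unavailable``. Rules are an ordered
    table of case-insensitive substrings mapped to ``target_city`` or
    ``other_us``; the first match wins. A non-blank string that matches no
    rule (including any generic-US patterns the rules carry) is
    ``unavailable`` — the category is evidence-based, never a default guess.
    """
    if profile_location is None or not profile_location.strip():
        return LocationCategory.UNAVAILABLE
    haystack = profile_location.lower()
    for needle, category in rules:
        if needle.lower() in haystack:
            return category
    return LocationCategory.UNAVAILABLE


def load_location_rules(source: Union[str, IO[str]]) -> list[tuple[str, LocationCategory]]:
    """Load an ordered location-rule table from YAML.

    Expected form: a list of one-entry mappings, e.g.::

        - "new orleans": target_city
        - "nola": target_city
        - ", la": target_city
        - "usa": other_us
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    rules: list[tuple[str, LocationCategory]] = []
    for entry in doc or []:
        if not isinstance(entry, Mapping) or len(entry) != 1:
            raise TranscriptError(f"malformed location rule: {entry!r}")
        (needle, cat), = entry.items()
        rules.append((str(needle), LocationCategory(str(cat))))
    return rules


CANONICAL_COLUMNS = ["tweet_id", "author", "text", "created_at", "kind"]


def write_transcript(tweets: Sequence[Tweet], path: Union[str, IO[str]]) -> None:
    """Write the normalized transcript as CSV with canonical columns
    (tweet_id, author, text, created_at ISO-8601, kind)."""
    frame = pd.DataFrame(
        {
            "tweet_id": [t.tweet_id for t in tweets],
            "author": [t.author for t in tweets],
            "text": [t.text for t in tweets],
            "created_at": [t.created_at.isoformat() for t in tweets],
            "kind": [classify_tweet(t).value for t in tweets],
        }
    )
    frame.to_csv(path, index=False)
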