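"""Theme coding of original tweets and inter-coder reliability.

The coding scheme is an adapted Information-Community-Action framework:
three substantive themes — information sharing, positive affect /
interpersonal closeness, action / activism / advocacy — made exhaustive by
an unable-to-determine category, with four subthemes (health information,
health opinion, health experience, asking) existing only under information
sharing. Retweets are excluded from coding to avoid biasing the theme
distribution toward whatever the hosts amplified.

Agreement between two coders is scored three ways: raw percent agreement,
Cohen's kappa (chance agreement from each coder's own marginal label
distribution) and Scott's pi (chance agreement from the pooled marginal).
Kappa and pi coincide exactly when the two coders' marginals are identical,
and kappa >= pi otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Iterable, Optional, Sequence

import pandas as pd

from .transcript_io import Tweet, TweetKind, classify_tweet

THEMES = (
    "information_sharing",
    "positive_affect_interpersonal_closeness",
    "action_activism_advocacy",
    "unable_to_determine",
)

SUBTHEMES = (
    "health_information",
    "health_opinion",
    "health_experience",
    "asking",
)


class CodingError(ValueError):
    """Invalid coded label or a coded tweet that violates the protocol."""


@dataclass(frozen=True)
class CodedTweet:
    """One coder's label for one original tweet. ``subtheme`` is set iff the
    theme is information sharing."""

    tweet_id: str
    coder_id: str
    theme: str
    subtheme: Optional[str] = None

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise CodingError(f"unknown theme {self.theme!r}")
        if self.theme == "information_sharing":
            if self.subtheme not in SUBTHEMES:
                raise CodingError(
                    f"information_sharing requires a subtheme, got {self.subtheme!r}"
                )
        elif self.subtheme is not None:
            raise CodingError(f"theme {self.theme!r} admits no subtheme")


@dataclass(frozen=True)
class ReliabilityResult:
    percent_agreement: float
    cohen_kappa: float
    scott_pi: float
    n_items: int


def theme_distribution(
    coded: Sequence[CodedTweet], tweets: Sequence[Tweet]
) -> pd.DataFrame:
    """Counts and one-decimal percents per theme and subtheme over the
    reconciled coding.

    ``coded`` must hold exactly one (reconciled) label per coded tweet and
    may only reference tweets classified as original; a label pointing at a
    retweet raises :class:`CodingError`. Percents use the number of original
    tweets in the transcript as denominator, which is reported in every row.

    One-decimal percents are truncated toward zero (314 of 491 displays
    63.9, not 64.0), so a displayed share never overstates the exact one;
    counts are always alongside for exact arithmetic.
    """
    kinds = {t.tweet_id: classify_tweet(t) for t in tweets}
    n_original = sum(1 for k in kinds.values() if k is TweetKind.ORIGINAL)
    seen: set[str] = set()
    for c in coded:
        if c.tweet_id not in kinds:
            raise CodingError(f"coded tweet_id {c.tweet_id!r} not in transcript")
        if kinds[c.tweet_id] is TweetKind.RETWEET:
            raise CodingError(f"coded tweet_id {c.tweet_id!r} is a retweet")
        if c.tweet_id in seen:
            raise CodingError(f"duplicate reconciled label for {c.tweet_id!r}")
        seen.add(c.tweet_id)

    theme_counts = Counter(c.theme for c in coded)
    sub_counts = Counter(c.subtheme for c in coded if c.subtheme is not None)

    def pct(count: int) -> float:
        if n_original == 0:
            return 0.0
        return (count * 1000 // n_original) / 10

    rows = []
    for theme in THEMES:
        rows.append(
            {
                "theme": theme,
                "subtheme": None,
                "count": theme_counts.get(theme, 0),
                "percent": pct(theme_counts.get(theme, 0)),
                "denominator": n_original,
            }
        )
        if theme == "information_sharing":
            for sub in SUBTHEMES:
                rows.append(
                    {
                        "theme": theme,
                        "subtheme": sub,
                        "count": sub_counts.get(sub, 0),
                        "percent": pct(sub_counts.get(sub, 0)),
                        "denominator": n_original,
                    }
                )
    return pd.DataFrame(rows)


def _check_aligned(a: Sequence[Hashable], b: Sequence[Hashable]) -> None:
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty label vectors")


def percent_agreement(coder_a: Sequence[Hashable], coder_b: Sequence[Hashable]) -> float:
    """Share of aligned items with matching labels, in percent."""
    _check_aligned(coder_a, coder_b)
    matches = sum(1 for x, y in zip(coder_a, coder_b) if x == y)
    return matches / len(coder_a) * 100.0


def cohen_kappa(coder_a: Sequence[Hashable], coder_b: Sequence[Hashable]) -> float:
    """Cohen's kappa: chance-corrected agreement with expected agreement
    from the two coders' separate marginal distributions.

    When expected agreement is 1 (each coder used a single label), kappa is
    1 if observed agreement is also 1, otherwise undefined (raises).
    """
    _check_aligned(coder_a, coder_b)
    n = len(coder_a)
    p_o = Fraction(sum(1 for x, y in zip(coder_a, coder_b) if x == y), n)
    marg_a = Counter(coder_a)
    marg_b = Counter(coder_b)
    p_e = sum(
        Fraction(marg_a[label], n) * Fraction(marg_b.get(label, 0), n)
        for label in marg_a
    )
    if p_e == 1:
        if p_o == 1:
            return 1.0
        raise ZeroDivisionError("kappa undefined: expected agreement is 1")
    return float((p_o - p_e) / (1 - p_e))


def scott_pi(coder_a: Sequence[Hashable], coder_b: Sequence[Hashable]) -> float:
    """Scott's pi: chance-corrected agreement with expected agreement from
    the pooled marginal, ``p_e = sum_c ((n_a(c) + n_b(c)) / 2N)^2``."""
    _check_aligned(coder_a, coder_b)
    n = len(coder_a)
    p_o = Fraction(sum(1 for x, y in zip(coder_a, coder_b) if x == y), n)
    pooled = Counter(coder_a) + Counter(coder_b)
    p_e = sum(Fraction(c, 2 * n) ** 2 for c in pooled.values())
    if p_e == 1:
        if p_o == 1:
            return 1.0
        raise ZeroDivisionError("pi undefined: expected agreement is 1")
    return float((p_o - p_e) / (1 - p_e))


def _aligned_labels(
    coded: Iterable[CodedTweet], coder_a: str, coder_b: str, level: str
) -> tuple[list[str], list[str]]:
    by_coder: dict[str, dict[str, CodedTweet]] = {coder_a: {}, coder_b: {}}
    for c in coded:
        if c.coder_id in by_coder:
            by_coder[c.coder_id][c.tweet_id] = c
    common = sorted(set(by_coder[coder_a]) & set(by_coder[coder_b]))
    if not common:
        raise ValueError(f"no tweets coded by both {coder_a!r} and {coder_b!r}")

    def label(c: CodedTweet) -> str:
        if level == "theme":
            return c.theme
        # Subtheme level: items outside information sharing collapse into a
        # single "other" bucket so every coded item still contributes.
        return c.subtheme if c.subtheme is not None else "other"

    return (
        [label(by_coder[coder_a][tid]) for tid in common],
        [label(by_coder[coder_b][tid]) for tid in common],
    )


def coding_reliability(
    coded: Iterable[CodedTweet],
    coder_a: str,
    coder_b: str,
    level: str = "theme",
) -> ReliabilityResult:
    """Agreement statistics between two coders' pre-reconciliation labels,
    aligned by tweet_id.

    ``level`` is ``"theme"`` or ``"subtheme"``; at subtheme level, items a
    coder placed outside information sharing count as one "other" category.
    """
    if level not in ("theme", "subtheme"):
        raise ValueError(f"level must be 'theme' or 'subtheme', got {level!r}")
    a, b = _aligned_labels(coded, coder_a, coder_b, level)
    return ReliabilityResult(
        percent_agreement=percent_agreement(a, b),
        cohen_kappa=cohen_kappa(a, b),
        scott_pi=scott_pi(a, b),
        n_items=len(a),
    )
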