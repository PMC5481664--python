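import io
from datetime import datetime
from zoneinfo import ZoneInfo

import pytest
from hypothesis import settings

import hashchat as hc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

CT = ZoneInfo("America/Chicago")


def ct(hour: int, minute: int = 0, second: int = 0) -> datetime:
    """A timestamp on the canonical chat day, Central Time."""
    return datetime(2015, 3, 5, hour, minute, second, tzinfo=CT)


@pytest.fixture
def small_csv() -> io.StringIO:
    """Three-row transcript with handle/text/time columns."""
    return io.StringIO(
        "author,text,created_at\n"
        "@FitNOLA,Join us at noon #LiveFitNOLA,2015-03-05T12:01:00\n"
        "alice,hi @bob how are you,2015-03-05T12:02:00\n"
        "bob,RT @alice: hi @bob how are you,2015-03-05T12:03:00\n"
    )


@pytest.fixture
def mini_tweets() -> list[hc.Tweet]:
    """Hand-built four-tweet transcript: reciprocal pair, a retweet, a self
    mention."""
    return [
        hc.Tweet("t1", "alice", "hi @bob", ct(12, 1)),
        hc.Tweet("t2", "bob", "hi @alice", ct(12, 2)),
        hc.Tweet("t3", "carol", "RT @bob: thanks @dave", ct(12, 3)),
        hc.Tweet("t4", "alice", "note to self @alice", ct(12, 4)),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale simulated chat (66 participants, ~744 tweets)."""
    return hc.simulate_chat(hc.ChatSimSpec(seed=20150305))
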