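# hashchat

Engagement analysis for hashtag-bound Twitter chats — the prearranged,
time-boxed, moderated conversations public health organizations run under a
shared hashtag with one or two host accounts.

`hashchat` turns a chat transcript into a directed **mention multigraph**
(one edge per tweet per distinct `@username` mentioned, retweets included,
self mentions kept) and computes, per account:

- **engagement ratio** — the out:in mention ratio normalized so the smaller
  side is 1 and the larger side is rounded to the nearest integer. A host
  with 63 outgoing and 38 incoming mentions has ratio 2:1; a popular guest
  with 8 outgoing and 19 incoming has 1:2.
- **return on engagement (ROE)** — `(in − out) / out × 100`, the engagement
  gain or loss relative to the engagement invested, undefined (never
  infinite) when the account sent no mentions.
- **depth and breadth** — per-counterpart mention multiplicity versus number
  of distinct counterparts, which distinguishes broad-scale engagement from
  a repeated one-on-one exchange at the same ratio.

Around those metrics it provides transcript parsing and normalization
(handle grammar, `RT @` retweet detection, chat-window filtering, location
categorization), Louvain-style community detection with seeded
reproducibility and per-community connection shares, management and scoring
of two-coder thematic content coding (percent agreement, Cohen's κ, Scott's
π) under an adapted Information–Community–Action scheme, and a synthetic
chat generator with an exact ground-truth ledger so the entire pipeline is
testable without any platform data.

## Worked example

```python
import hashchat as hc

# a 66-participant hosted chat, ~744 tweets in 75 minutes, 34% retweets
tweets, ledger = hc.simulate_chat(hc.ChatSimSpec(seed=1))
network = hc.build_network(tweets)

print(len(tweets), network.number_of_nodes(), network.number_of_edges())
# 764 102 632

table = hc.engagement_table(network, tweets, ["tulaneprc", "fitnola"])
print(table[["handle", "n_tweets", "out_degree", "in_degree", "ratio",
             "roe_display"]].to_string(index=False))
#    handle  n_tweets  out_degree  in_degree ratio  roe_display
# tulaneprc        52          53         56   1:1            6
#   fitnola        61          47         43   1:1           -9
```

764 tweets produced a network of 102 members (authors plus everyone they
mentioned) and 632 mentions. Both hosts here sit near engagement balance
(ratio 1:1): the first invested 53 outgoing mentions and received 56 back,
a +6% return on engagement, while the second received 4 fewer than it sent,
a −9% return (display values are half-away-from-zero rounded; raw values
stay in the `roe_raw` column).

Direct metric calls reproduce a published-style engagement table from its
degree pairs alone:

```python
>>> str(hc.engagement_ratio(63, 38)), hc.roe_display(63, 38)
('2:1', -40)
```

The same analysis runs from a shell:

```sh
hashchat simulate --seed 1 --out chat/
hashchat analyze --transcript chat/transcript.csv \
    --start 2015-03-05T12:00 --end 2015-03-05T13:15 --tz America/Chicago \
    --focus @tulaneprc,@fitnola --seed 1 --out report/
```

which writes participant characteristics, the network summary, the
engagement table, community assignments and shares, GraphML/GEXF exports,
and a run-metadata record of every seed and rounding rule.

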