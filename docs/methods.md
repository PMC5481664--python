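# Methods

## The mention network

A hashtag chat is modeled as a directed multigraph. Every tweet by author
*a* containing `@u` contributes one edge *a → u* per **distinct** handle
mentioned in that tweet: repeated mentions of the same handle inside one
(140-character-era) tweet are collapsed, because a mention records that the
author addressed that user in that tweet, and per-occurrence counting is
not meaningfully distinguishable at tweet length. Parallel edges across
tweets are kept — depth analysis requires the multiplicity — and a
simple-graph view is only ever a projection.

Retweets generate edges exactly like originals: the rendered text
`RT @author: …` makes the retweeter mention the retweeted author plus every
handle in the quoted text. This is what lets hosts-retweeting-hosts inflate
an out-degree and depress an ROE (the echo-chamber mechanism; see the
acceptance property below). Self mentions are retained as self edges and
add one to both the out-degree and the in-degree of the node.

Nodes are all tweet authors plus all mentioned handles, so a silent-but-
mentioned account and a never-mentioned author both appear.

A mention is a maximal `@` + 1–15 word characters token whose `@` is at
start-of-string or preceded by a non-word character (so e-mail addresses do
not match, and a 16-character token is not a mention at all). Handles are
normalized to lowercase without the `@`; normalization is idempotent.
Retweet classification uses a source-provided flag when present, else the
case-insensitive `RT @handle` prefix; quote markers other than `RT` count
as original. The chat window is half-open, `start ≤ t < end`, evaluated in
the transcript's declared timezone; naive timestamps are localized to it,
aware ones converted.

## Engagement ratio and ROE

For an account with out-degree *o* and in-degree *i*:

- ROE = (*i* − *o*) / *o* × 100, in percent; undefined when *o* = 0
  (reported as a flag, never as infinity — the formula divides by the
  engagement invested).
- Engagement ratio: the smaller raw side is normalized to 1 and the larger
  side carries round(max/min) with a floor of 1; equal degrees give 1:1,
  and a zero on one side gives 0 on that side and 1 on the other.

Display rounding of ROE and of the ratio's larger side is **half away from
zero** (−17.5 → −18, 137.5 → 138), implemented in exact rational
arithmetic so boundary halves never drift in binary floats. Raw unrounded
values are always carried alongside display values; nothing downstream ever
consumes a rounded number.

Depth and breadth qualify a ratio: breadth-out is the number of distinct
targets, max-depth-out the largest per-counterpart multiplicity. 32
outgoing mentions to 31 distinct users plus oneself is broad-scale
engagement; 31 mentions of one user is a single-source exchange, and the
two can share a ratio and an ROE.

## Communities

The directed multigraph is projected to an undirected weighted simple graph
— the weight of {u, v} is the number of directed parallel edges in either
direction, self loops kept — and partitioned by Louvain modularity
maximization (networkx implementation) at resolution 1.0 with a mandatory
seed; a fixed seed yields a byte-identical assignment. Community ids are
renumbered canonically by each block's smallest member handle, so ids do
not depend on optimizer iteration order. An optional restart count reruns
the optimizer with derived seeds and keeps the best-modularity partition;
on small graphs (≤ 7 nodes) 20 restarts reach the exhaustive-enumeration
optimum on every fixture graph in the suite, which the acceptance tests
verify by enumerating all set partitions.

A community's **connection share** is the percent of all directed edges
with both endpoints inside it (one decimal); cross-community edges are
reported separately, and the either-endpoint share is emitted alongside as
an alternative reading — it is the reading under which strongly
host-attracted chats put a majority of edges on the two host communities.

## Content coding and reliability

Original tweets (retweets excluded, to avoid letting amplification bias the
distribution) are coded with one of three substantive themes — information
sharing, positive affect / interpersonal closeness, action / activism /
advocacy — plus unable-to-determine, with four subthemes (health
information, health opinion, health experience, asking) only under
information sharing. The store keeps per-coder labels and a reconciled
column; agreement statistics are always computed on the pre-reconciliation
labels.

Percent agreement, Cohen's κ (expected agreement from the two coders'
separate marginals) and Scott's π (expected agreement from the pooled
marginal) are computed in exact fractions. κ = π when the coders' marginals
coincide and κ ≥ π otherwise. When expected agreement is exactly 1, the
statistic is 1 if observed agreement is 1 and undefined otherwise. At
subtheme level, items a coder placed outside information sharing form a
single "other" category so every jointly coded item contributes.

Display convention: one-decimal theme percents are **truncated** toward
zero (314/491 → 63.9), so a displayed share never overstates the exact
value; integer percents elsewhere (participant characteristics, original-
tweet share) use half-away-from-zero rounding. Consequence: one-decimal
theme percents can sum to slightly under 100 (up to 0.1 per theme row).

## The synthetic chat generator

`ChatSimSpec` defaults describe the emulated study conditions: 66
participants, two hosts, a 75-minute early-afternoon window, an overall
mean of 744/66 ≈ 11.3 tweets per participant, retweet probability 0.34, a
mention-count distribution over {0, 1, 2, 3} with mean ≈ 0.29 per original
tweet (chosen so total mentions land near 474 given that retweets add the
retweeted author), 69 mentioned-but-silent bystander accounts (so the
member count lands near 135 = 66 + 69), host attraction 14 (hosts ≈ 14×
more likely to be mentioned, putting roughly a sixth of incoming mentions
on the two hosts), hosts tweeting at 6× the non-host intensity (their
published tweet counts are ≈ 7× the mean; intensities are rescaled so the
expected total is unchanged), theme probabilities equal to the reconciled
coding proportions (e.g. information sharing 314/491), self-mention
probability 0.01, and profile locations drawn 39:15:12 over target-city /
other-US / undisclosed.

Per participant the tweet count is Poisson; timestamps are uniform in the
window; a retweet copies a uniformly chosen earlier tweet (rendered
`RT @author: text`, falling back to an original when no earlier tweet
exists); an original draws mention targets without replacement with hosts
upweighted. Text is assembled from a small template bank with real mention
tokens injected, so parsing is exercised on text, never on ledger
shortcuts; the ledger records the exact per-tweet edge set, per-user
counts, and per-original theme, and `recover_and_compare` verifies the
transcript→network round trip is exact and localizes any induced mismatch
to its tweet id.

The echo-chamber knobs (`echo_host`, `echo_target`, `echo_prob`) make one
host retweet the other at a controlled rate; raising the rate provably
raises the echoing host's out-degree and lowers its ROE monotonically in
expectation (checked over 50 seeds per level).

What the generator does **not** emulate: real language, reply threading,
follower structure, temporal bursts around chat questions, bot traffic, or
coder disagreement patterns (ledger themes are single ground-truth labels).
Passing tests therefore demonstrate correctness of parsing, accounting,
metrics and detection on structurally realistic traffic — not robustness to
the full messiness of platform exports.

## Numerical and procedural choices

- Rounding: half away from zero everywhere a display integer is produced
  (ROE, ratio side, means, integer percents); truncation only for
  one-decimal theme percents, as above. Exact `Fraction` arithmetic at all
  rounding boundaries.
- Standard deviations are sample SDs (ddof = 1), 0 for fewer than two
  observations; the convention is written into every output metadata
  record.
- Network summary means are reported raw and display-rounded; integer
  counts exactly.
- Degenerate inputs: empty networks summarize to zeros; an empty partition
  request on an empty network raises; ROE/ratio undefined cases raise
  typed errors that the table layer converts to flags.
- Per-user tweet counts in the engagement table are counted within the
  analysis window, and the run metadata says so.
- Participant location uses the first non-blank self-disclosed string per
  author; rules are ordered case-insensitive substring matches mapping to
  target-city or other-US, first match wins, no match (or blank) →
  unavailable.
- The reporting layer re-runs byte-identically for a fixed config and seed;
  every filter logs its in/out counts at INFO so transcript accounting
  (e.g. total → originals) is auditable.
- Acceptance-scale choices: property checks run 200 simulated chats at the
  default (study-scale) conditions for conservation and round-trip
  invariants, 50 seeds per level for the echo-chamber monotonicity, and
  exhaustive partition enumeration up to 7 nodes for modularity optimality.

## Known limitations

- Mention extraction follows the classic username grammar; platform
  variants (longer handles, internationalized names) would need a wider
  grammar.
- Retweet detection sees only `RT @` prefixes and explicit flags; quote
  tweets and manual "via @user" attributions count as originals.
- Louvain is a heuristic: on large graphs the returned partition is a
  high-modularity local optimum, reproducible for a seed but not guaranteed
  globally optimal (restarts mitigate on small graphs, where the tests
  prove optimality by enumeration).
- The engagement ratio's integer display is coarse for small degrees (the
  rounded label of 19:8 and 2:1 are identical); interpretation should lean
  on the raw degrees and ROE alongside.
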