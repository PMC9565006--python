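# Methods

## Problem and data model

The pipeline measures the prevalence of *quit-vaping mentions* in a
keyword-collected e-cigarette tweet stream across three windows around the
FDA cartridge-flavor enforcement policy, and compares the windows
statistically. A corpus is line-delimited JSON with six fields per tweet
(`tweet_id`, `user_id`, `created_at`, `text`, `country_code`,
`has_profile_face`); this is a deliberate minimal dialect of the Twitter
streaming-API record — full API payloads carry nothing the analysis uses.
Timestamps are accepted in ISO-8601 or the classic
`Day Mon DD HH:MM:SS +0000 YYYY` form and canonicalised to UTC; window
membership is decided on the UTC calendar date, inclusive on both ends.

Demographics arrive as a separate per-user CSV (`user_id`, `age`, `gender`,
`face_valid`), the interface one would fill from a face-recognition run on
profile images. Rows are valid only when exactly one face was detected
(`face_valid`); the pipeline itself never does image inference.

## Filtering

Three pure per-tweet predicates (hence idempotent and order-independent):

* **relevance** — the text matches an e-cigarette keyword. The keyword list
  ships verbatim in the default config. Matching is case-insensitive on
  punctuation-normalised text: single-word terms match whole tokens,
  multi-word terms (`free shipping`, and hyphenated terms like `e-cig`,
  which normalise to two tokens) match consecutive token phrases, and the
  symbols `$` and `%` match as raw substrings. Token matching is a
  deliberate choice the source text of the method leaves open: it stops
  promo term `deal` from firing inside `dealing`, while `dealer` remains its
  own term. Relevance is re-applied on ingest so arbitrary JSONL inputs
  behave like a keyword-collected stream.
* **US geolocation** — `country_code == "US"`; a missing code excludes the
  tweet (conservative: only positively identified US tweets enter).
  Geocoding free-text profile locations is out of scope; the country field
  is taken as given.
* **non-commercial** — tweets matching a promotion keyword are removed.

Tweets dated outside all three windows (notably Aug–Dec 2019, confounded by
state-level flavor bans) are excluded from every tally. Retweets and
near-duplicates are *not* collapsed — every record counts once, matching the
source method; only exact duplicate `tweet_id`s are dropped on read.

## Lexicon mining

Each tweet becomes a *transaction*: punctuation → spaces, lowercase,
whitespace-split, stopwords removed, deduplicated. The stopword list ships
in the config: a documented core list plus a standard function-word
extension (the original list was stated as open-ended; ours is explicit and
editable).

Frequent itemsets (absolute support ≥ `min_support`, default 1000 — the
published thresholds are clearly absolute counts) are mined with FP-growth,
implemented from scratch: items ordered by descending global frequency with
lexicographic tie-breaks (a deterministic tree shape), recursive
conditional-tree mining, exact supports. Equivalence with exhaustive subset
enumeration is asserted over randomized corpora in the test suite; the
enumeration oracle lives in the tests and is never used in the pipeline.

For every frequent pair {x, y} both directed rules are scored by confidence
`P(consequent | antecedent) = support(pair)/support(antecedent)`. The
cessation lexicon is the set of antecedents whose consequent is the anchor
token `vaping` with support ≥ 1000 and confidence ≥ 0.30, sorted by support.
Two documented conventions: the rule direction is keyword → *vaping* (the
published description of "association with vaping" does not fully pin the
direction down), and threshold comparisons are inclusive — forced by the
fact that the retained *quit* rule sits at exactly 0.30. Mining is optional
at analysis time (`--mine`); by default the shipped lexicon
(`quit`, `stop`) is used, since the original study mined once to fix it.

## Classification

Lemmas are expanded through a fixed suffix table (-s, -ing, -ed with
final-e dropping and CVC final-consonant doubling, where a `qu` onset counts
as a consonant): quit → {quit, quits, quitting, quitted}, stop → {stop,
stops, stopped, stopping}. The original "variants" were never enumerated;
a fixed, configurable table favours reproducibility over guessing. A tweet
is a quit mention iff its token set intersects the variant set. No
co-occurring vaping token is required (the corpus is already e-cigarette
filtered, and real quit mentions often name the product otherwise), and
negation is not handled — fidelity to the source method, and a known
limitation. `label_corpus` uses a compiled alternation over normalised text;
a test asserts it equals per-tweet token membership.

## Statistics

Per window: tweet count, quit-tweet count, unique users, unique users with
≥ 1 quit tweet. Users are deduplicated within windows only — an account
active in two windows contributes to both denominators. Whether quit *users*
should additionally be deduplicated across windows is ambiguous in the
source (its per-window quit-user counts sum exactly to its overall unique
total); both conventions are implemented
(`--dedup-users-across-periods`), defaulting to within-window only.

Windows are compared with the pooled two-proportion z-test, two-sided (the
conventional default; sidedness was unstated). Degenerate pooled variance
(all successes or all failures) reports z = 0, p = 1 with a warning.
Percentages are rounded half-up to two decimals. No multiple-testing
correction is applied, matching the source analysis.

Demographic breakdowns use only valid single-face records with inferred age
≥ 18. The young-adult bin is the half-open interval [18, 35): the published
bins "18 to 35" and "35 and above" overlap at 35, and we assign 35 to the
older bin. Windows with zero inferrable users are flagged and skipped in
pairwise tests.

## Synthetic corpus generator

The generator emits the statistical structure the analysis assumes, with
ground truth, so every downstream stage is testable without any data
download. Per window: a fixed number of users, each posting a
zero-truncated-Poisson number of tweets (an activity model the source does
not specify; it is the simplest one exposing the tweet-level vs user-level
proportion gap), timestamps uniform in the window. Quit status is assigned
per tweet (never to commercial tweets) at the window's configured rate;
user-level quit status emerges downstream, as in the real tally. Country is
a user-level attribute, so the quit rate holds among US tweets regardless of
the geographic mix. Texts are assembled from a filler vocabulary screened to
contain no cessation or promotion term; every text embeds one e-cigarette
keyword, quit texts embed a lexicon variant (or, at a configurable
`synonym_fraction`, an out-of-lexicon cessation phrase — a negative control
whose missed recall the tests document), commercial texts a promotion
snippet. Labels and text therefore agree by construction, which is what
makes classifier precision/recall = 1.0 an *exactness* check rather than an
empirical claim about real language.

Defaults are the observed study conditions at one tenth of the original
corpus: per-window quit rates 0.0011 / 0.0020 / 0.0024, users
12,674 / 4,837 / 18,969 (the published user denominators ÷ 10),
tweets-per-user means 1.31 / 3.50 / 3.65 (published tweet/user ratios), and
a 10.24% demographic-inferability rate. Quantities the study never reports
for the full corpus are assumptions, documented as such, not estimates:
commercial fraction 0.10, non-US fraction 0.25, female fraction 0.40 and
young-adult fraction 0.85 (the latter two echo the composition observed
among quit-mentioners). Ages are a uniform(18, 35)/uniform(35, 70) mixture —
only the two-bin split is ever consumed. Tweet ids are seed-dependent
strictly increasing integers; identical seeds give byte-identical corpora.

What the generator does **not** emulate: real language (so mining a
synthetic corpus at study-scale thresholds does not re-derive the lexicon —
each synthetic text carries one uniformly chosen e-cigarette keyword, not
the real co-occurrence structure around *vaping*; lexicon re-derivation is
instead exercised on small corpora constructed with a known co-occurrence
structure), retweet/network structure, temporal burstiness, negated quit
talk, and users active in more than one window. Passing tests on synthetic
corpora therefore validate the *mechanics* of the pipeline and its
statistics, not the construct validity of quit-mention measurement on real
tweets.

## Problem sizes and numerical choices

Test and script workloads run at one tenth of the original denominators
(~100k tweets per corpus) or below; the parameter-recovery check uses 20
seeded replicates at tenth scale and asserts that the configured rates are
recovered within 3 binomial standard errors together with a significant
pre-vs-post test in ≥ 95% of replicates — at these sizes the pre-vs-post
power is ≈ 95%, so this bound is expected to sit near its edge. The mining
oracle check uses corpora of ≤ 200 transactions over ≤ 12 items, where
exhaustive enumeration is itself cheap and trustworthy. Percentage rounding
is decimal half-up (not banker's); z-tests use exact closed forms with
p = 2·Φ̄(|z|). Malformed corpus lines are skipped and counted, but a file
that is more than half malformed is rejected as a whole.

## Known limitations

Keyword lexicons measure *mentions of* quitting, not quitting; negation,
sarcasm, and co-occurring COVID-era confounders pass through undetected.
Geolocation and demographic inference are taken as given inputs with their
own error structure. The synthetic generator's independence assumptions
(users independent, one window each, labels independent across tweets) make
its standard errors exactly binomial — real data would be overdispersed.
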