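# Methods

## Corpus model

A corpus is one community's threads. Posts carry 1-based positions;
position 1 is the original post and the only one that may have a title.
Positions must be contiguous (gaps are treated as data errors rather
than silently re-indexed, so deletions in a source scrape surface
loudly). Threads without any reply to the original post carry no drift
information and are removed before analysis; all statistics
(mean/median/max thread length, member counts) are computed on the
filtered corpus. Records arriving unsorted are ordered by
(thread_id, position), tie-broken by timestamp and then input order;
duplicate (thread_id, position) pairs are an error.

## Vector space and similarity

Each post body (titles are never vectorized — title conventions carry
different pragmatics than body text) is tokenized by lowercasing and
splitting on any non-alphanumeric character; pure-digit tokens are
kept, and no stemming or stopword removal is applied by default. The
rationale for skipping stopword lists: idf is computed at the
*community* level with one post per document, so terms that pervade a
community are already down-weighted, and an explicit list would be one
more unstated degree of freedom.

The weighting is tf·idf with tf the raw within-post count and
idf = ln(N/df), N the number of posts the community model was fitted
on and df the number of posts containing the term. There is no
smoothing and no +1 shift: a term present in every post carries zero
weight, which is the behaviour we want from a drift measure (ubiquitous
words say nothing about topic). `smooth_idf` (ln((1+N)/(1+df))) and
`sublinear_tf` (1 + ln tf) are available as configuration for
sensitivity analyses, and the fitted model serializes to JSON
(N, df, config) so any run can be reproduced bit for bit.

Similarity is the cosine of two weight vectors, which normalizes text
length: concatenating a post with itself leaves all its similarities
unchanged (a property test enforces this to 1e-12). Zero vectors
(empty bodies, out-of-vocabulary posts) get similarity 0 by convention
— "no shared terms" — so trajectories are total. Because weights are
nonnegative, cosine lies in [0, 1]; the implementation clips at 1 to
absorb float rounding on identical vectors.

The sparse implementation is checked against an independent dense
brute-force tf-idf/cosine oracle (and scikit-learn's
`cosine_similarity`) on a thousand random micro-corpora to 1e-12.

## Drift detection

For each thread of length L ≥ 2 the similarity trajectory holds, at
every position p ∈ 2..L, the cosine to the original post
(sim_to_first) and to the immediately preceding post (sim_to_prev).
Position 1 has no point: self-similarity is identically 1.

The corpus-wide baseline is the arithmetic mean of sim_to_first at
each position, retained only where at least `min_support` posts
contribute (default 50, the figure-construction rule; tests use 1–3).
Conversation naturally wanders, so the expected similarity declines
with position; comparing a post to the average *at its own position*
separates "more drifted than conversation usually is by now" from the
natural decline. A post is classified as drift when

    sim_to_first < baseline_mean(position) − margin

with strict inequality and margin defaulting to 0 (the comparison is
stated by the method; the inequality direction at ties and the margin
are our choices — ties are not drift, and the margin is exposed for
operating-point tuning but never used by the shipped studies).
Requesting a position the baseline does not cover raises an error
directing the caller to lower `min_support` or skip uncovered points;
the batch API offers both behaviours explicitly.

The baseline's shape is summarized by ordinary least squares of the
positional means on ln(position), reported with R². At least three
retained positions are required; for constant input R² is defined as 1
(the fit is exact). Baselines are computed per community by default,
with pooling available in the CLI.

## Counteraction and roles

A counteraction event occurs at position p ≥ 3 when
sim_to_first(p) − sim_to_first(p−1) > ε (default ε = 0): the post is
more relevant to the opening post than its predecessor was, the
signature of someone steering the thread back. The comparison uses
sim_to_first at consecutive positions, not sim_to_prev: "closer to the
original than the previous post was" is a statement about two
distances to the original.

Members act in mutually exclusive per-thread roles with precedence
staff/MD (matched by moderator id) > original poster (own thread) >
power user > regular user. A power user is a non-moderator whose
community-wide post count strictly exceeds the moderators' average
post count (total moderator posts / number of moderators); ties
resolve to regular user ("more than" is strict). A community without
moderators has no defined threshold, so the power tier is disabled
with a warning.

Counteraction effort for a member in a thread is
(counteractions credited to the member) / (the member's replies in the
thread), where the original post never counts as a reply and an event
at position p is credited to the author of post p. Role summaries use
two-stage averaging — first each member's mean effort across their
threads in a role, then the mean over members — so prolific members do
not dominate the role average; the SD and the 95% CI
(mean ± 1.96·SD/√n, a normal approximation) are taken over member
means. Member-role observations across threads are treated as
independent.

Role comparisons: one Kruskal–Wallis H over all roles with ≥ 2 member
observations (roles below that are dropped with a warning), then all
pairwise two-sided Mann–Whitney U tests with Holm–Bonferroni adjusted
p-values. U is exact for tie-free samples of ≤ 20 per group and uses
the tie-corrected normal approximation otherwise. The rank-biserial
effect size is r = 1 − 2U/(n₁n₂) with U belonging to the first-listed
group, so the sign encodes direction (negative when the first group's
efforts are larger); pairs are reported in alphabetical role order and
consumers interested only in magnitude should take |r|. The reported
interval is a normal-approximation CI on the difference of member-mean
efforts (second minus first), labelled as such — it is not a
Hodges–Lehmann shift interval. Identical pooled samples short-circuit
to H = 0 rather than relying on the library's degenerate-case
behaviour.

## Lexicon flagging

Members name drift themselves, and those self-identifications are
useful anchors. The default lexicon enumerates inflections explicitly
rather than stemming: `hijack(ed|ing|er|s)` and `off[- ]topic`, matched
case-insensitively at word boundaries in post *bodies* (so "Hi, Jack"
never matches, and a keyword appearing only in a title is never a body
flag). Title matches are reported separately. The standalone token
"OT" is recognized only in original-post titles, where it is a
community convention for announcing a deliberately off-topic thread;
in bodies it is too ambiguous. Off-topic-titled threads can be
compared in length against the rest of the corpus with a Mann–Whitney
test plus rank-biserial r. The lexicon is user-replaceable and flags
export with ±1 post of context, because deciding whether a keyword
really marks drift (as opposed to, say, quoting the definition of
"OT") is a human judgment the tool deliberately does not automate.

## Evaluation arithmetic

Confusion matrices are counted per instance with the positive class
chosen by the caller (drift or counteraction). precision = tp/(tp+fp),
recall = tp/(tp+fn), accuracy = (tp+tn)/total, F1 the harmonic mean of
precision and recall. Zero denominators yield 0 with a warning — tiny
synthetic corpora hit these cases, and silence would hide a degenerate
classifier. Display rounding is half-up to two decimals; internal
values keep full precision, and JSON exports carry both.

## Synthetic corpus generator

The generator emulates the statistical structure the detectors assume
and provides the gold labels real scrapes lack. It is not a language
model: bodies are bags of synthetic word tokens, with no grammar,
discourse markers, or real vocabulary.

**Topic state.** Each community owns `n_topics` (100) topics of
`vocab_per_topic` (10) words; topic vocabularies are disjoint unless an
`overlap` fraction of each topic's words is drawn from a shared pool
(overlap 1 makes all topics indistinguishable and removes the signal —
in fact, with idf weighting, terms present in every post weigh zero).
A thread opens on a mixture over 3–4 topics (mean 3.44, floor/ceil
randomization; a narrow spread is deliberate, since the number of
active topics sets the whole thread's similarity level and a wide
spread would confound the positional baseline with thread verbosity).
Per step, a (1 − carryover) fraction of mixture mass moves to a fresh
topic, so the mass remaining on the original topics after the p−1
steps separating post p from the original is exactly carryover^(p−1) —
this is the closed form `expected_trajectory` returns, and the
generator records each post's original-topic mass in the labels
(`frac_original`) so Monte-Carlo checks compare like with like. Cosine
similarity is a monotone transform of this mass that coincides with it
at 0 and 1; its absolute scale depends on post length, which is why
the closed form is stated for the topic process rather than for raw
cosine. With probability `abrupt_drift` per reply the whole mixture is
replaced by fresh topics (a hijack); `hijack_position` forces this at
a fixed position for controlled experiments.

**Counteraction.** Once the conversation retains less than
`opportunity_threshold` (1/3) of the original topic mass — i.e. the
thread has *noticeably* drifted; gradual decay rarely triggers this,
abrupt replacement always does — each reply counteracts with a
role-dependent probability (`counteraction_probs`, defaults 0.6 / 0.45
/ 0.5 / 0.1 for original posters / staff / power / regular users,
ordered as moderated health forums behave). A counteracting post
displays the original mixture and, by default, puts the conversation
back on topic. With `dominant_drift=True` the drifted side
conversation persists despite interjected counteractions — topic
domination — which keeps the counteraction opportunity open at every
reply and makes per-role propensities directly identifiable from
effort = counteractions/replies.

**Labels.** `is_drift` is state-based: a post is labeled drifted while
the thread is in an abrupt-replacement state (set by a hijack, cleared
by a state-restoring counteraction). Gradual decay is never labeled
drift, mirroring the tolerance of ordinary topic wander; the
classifier's false positives on heavily decayed gradual posts are
therefore genuine errors, not label noise. `is_counteraction` marks
exactly the posts that restored the original mixture.

**Structure around the text.** Thread lengths are
min + (geometric − 1), clipped to [2, 99], with mean 6.76 — matching
moderated-health-forum thread-length statistics (median ≈ 4–5, heavy
tail). Post length is lognormal (median 150 words, σ_log 0.3), scaled
by the number of active topics so the words-per-active-term sampling
density is comparable across posts; lengths this size keep multinomial
bag-sampling noise small relative to the drift signal, which is the
regime the term-overlap method assumes (and the regime real
paragraph-length posts are in). Replies are authored by the original
poster with probability 0.3, a moderator (12 per community) with
probability 0.05, and otherwise by a member drawn Zipf(1.5) from a
pool of twice the thread count — the heavy tail is what makes the
power-user tier non-empty, with roughly a dozen members exceeding the
moderators' average post count. Roles are derived from the realized
authorship schedule with exactly the rule the analysis module applies,
so gold roles and assigned roles agree by construction.

**Determinism.** All randomness flows through one numpy Generator
seeded from the config; the same seed yields byte-identical corpora
and labels.

## Study configurations

Two canned studies exercise the pipeline end to end (tests and
`scripts/acceptance.py`):

* **Detector recovery** — defaults (carryover 0.9, abrupt drift 0.15,
  disjoint vocabularies) at 500 threads. Drift classification against
  the state-based gold labels reaches F1 ≥ 0.9 and counteraction
  detection recall ≥ 0.9 at ε = 0; degrading the vocabulary separation
  (overlap → 1) collapses F1, confirming the detector feeds on topic
  structure rather than artifacts.
* **Role-effort recovery** — 300 threads of constant length 41 with
  `abrupt_drift=1`, `dominant_drift=True` and a doubled moderator reply
  share (0.10). Constant long threads matter because replies at
  position 2 structurally cannot counteract (events need a reply
  predecessor), which dilutes measured effort by 1/(L−1) — about 17%
  at natural thread lengths, 2.5% at length 41; the dominant-drift mode
  keeps the opportunity open at every reply; the moderator share gives
  each of the 12 moderators ≈ 100 replies so the smallest role tier has
  a standard error ≈ 0.02. Under this design the measured per-role
  efforts recover the generating propensities within ±0.05, and the
  original-poster-vs-regular-user contrast is significant at
  Holm-adjusted p < .05 with |r| > 0.5. This study scores effort
  against the generator's gold counteraction events, isolating the
  accounting and statistics from detector noise (the detector is scored
  separately above).

Problem sizes (500 / 300 threads, 1000 oracle micro-corpora) keep the
full suite and the acceptance script in the tens of seconds on one
CPU while leaving Monte-Carlo noise well inside the stated tolerances.

## What passing tests do and do not show

The synthetic corpus has disjoint (or controllably overlapping) topic
vocabularies, uniform within-topic word frequencies, no paraphrase,
no quoting, and drift that is exactly piecewise (gradual mass decay
plus full replacement). Real forum text has synonymy, quoting of
earlier posts (which inflates similarity), boilerplate signatures, and
drift that is rarely all-or-nothing. Detector recovery on the
generator therefore validates the *machinery* — vectorization,
baselines, classification rules, accounting, statistics — not the
real-world operating accuracy of term-overlap drift detection, which
on a hand-labeled forum gold standard sits around F1 ≈ 0.7 rather
than ≥ 0.9.

## Known limitations

* Term overlap only: no embeddings, no synonym handling; paraphrased
  returns to topic are invisible to the detector.
* The positional baseline needs volume; positions below `min_support`
  posts are unclassifiable by design.
* Within-member correlation across roles and threads is ignored
  (observations are treated as independent, as the two-stage averaging
  assumes).
* The CI conventions (normal approximation on member means and on
  mean differences) are symmetric approximations; with efforts bounded
  in [0, 1] and skewed, they can overshoot the unit interval for small
  groups.
* The lexicon is an explicit inflection list; misspellings and novel
  variants ("highjacked") are not matched unless added.
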