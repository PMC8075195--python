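# Methods

## Extraction model

Both extraction pipelines are rule systems over a structured per-sentence
summary rather than statistical classifiers. The summary (module
`vaxforum.parsing`) records tokens, lemmas, an approximate governor per
token, the subject noun phrase, the main verb, negation cues and their
attachment, and — per keyword — the adjectival and compound (noun-noun)
modifiers chaining into it. The parser is deterministic and shallow by
design: closed word classes (pronouns, determiners, auxiliaries,
prepositions, a small adjective inventory), a suffix-rule lemmatizer with an
exception table for the domain vocabulary, and left-attachment inside noun
phrases. It makes no attempt at clause embedding, coordination scope or
long-distance dependencies; its contract is correctness on the declarative,
single-clause sentence shapes the pattern tables target, and its failure
mode on other text is a missed match (which trades recall for precision, the
stated posture of the pipeline).

**Schedule filter.** A keyword ("schedule", "spacing") matches when its
vaccination context is established either by a context term among its own
modifiers/compounds ("vaccination schedule") or by a context term elsewhere
in the sentence provided the keyword carries no competing compound — the
competing-compound rule is what rejects "my work schedule" even in a
sentence that mentions vaccines. Compounds that are themselves polarity
markers ("CDC schedule") do not compete.

**Schedule classifier.** Default label *recommended*; flipped to
*alternative* by an alternative marker ("delayed", "selective",
"alternative", "modified", "spread out", "one at a time") or by a negation
attached to the matched clause; a negated alternative marker flips twice.
Negation attachment: "not"/"n't"/"never" flip iff they attach to the clause's
main verb; determiner "no" flips iff it heads the keyword phrase.
Clause-external negations do not flip. A comment's label is the union of its
sentence matches with alternative-over-recommended conflict resolution
(alternative markers are the specific signal; recommended is only a
default). All alternative approaches form one class; the method cannot
resolve sub-types.

**AEFI pipeline.** Same machinery with a reaction vocabulary (canonical
reaction → disjoint synonym lemmas) and an immunization-context sentence
constraint. *Negative experience* iff any attribution is non-negated;
*positive* iff all are negated. Classification is monotone: an added
non-negated attribution can only move a comment toward negative. Subject
resolution reads the subject noun phrase: acquaintance terms anywhere in the
phrase win (this places "my friend's kid" correctly), then a first-person-
possessed child-kinship head noun, then bare first-person singular;
everything else is `unknown`. Subject is a reported field, never a filter —
first- and second-hand experiences both count.

The keyword lists, marker sets, context constraints, reaction vocabulary and
kinship tables ship as editable YAML (`vaxforum/data/`); the architecture
(pattern + default/flip), not any particular list, is the load-bearing part,
and deployments on other platforms are expected to re-tune the lists.

## User aggregation

Unanimous comment labels propagate directly; discordant labels resolve by
majority; an exact tie resolves to the chronologically latest comment (a
user's most recent statement is their best current description). The rule is
injectable (`aggregate_schedule_labels(rule=...)`) because any fixed choice
here is a judgment call. A user reports negative experiences iff any of
their AEFI comments is a negative experience. Activity span τ is whole days
between first and last comment; single-day users are flagged and excluded
from τ summaries. Replies received (I_p) counts comments under the user's
authored posts; "comments received per authored post" is one of two
readings of that statistic and is the documented one here.

The prolificacy curve uses Wilson 95% intervals (well-behaved near 0/1 and
at small class counts) and default class bounds at powers of two
(0,1], (1,2], (2,4], (4,8], (8,∞); both are parameters.

## Association machinery

Odds ratios use the Woolf log-normal interval
`exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d))`; a single zero cell gets the
Haldane–Anscombe 0.5 correction and is flagged; doubly-degenerate tables
raise. Fisher's exact test is two-sided by the probability-mass definition
(sum of hypergeometric probabilities of tables no more probable than the
observed one, with the conventional 1e-7 relative tie tolerance); the test
suite checks it against an exact-rational enumeration oracle. The group
screen retains groups whose per-group 95% CI excludes 1, deliberately
without multiple-testing correction (the screen is descriptive; a
Benjamini–Hochberg pass can be layered on the returned Fisher p-values).
Cohen's κ is computed from marginal frequencies and cross-checked against
scikit-learn in tests. Domain reduction defaults to full host minus a
leading `www.` (so `pediatrics.aappublications.org` survives as listed);
a registrable-domain mode with a small built-in multi-part-suffix table is
available. Geolocation resolves the self-reported location first (trailing
state abbreviation, then any full state name), with state-named local
groups as fallback; on conflict the self-report wins and the source is
recorded as `both`. The 51-row state table with 2010 census populations is
packaged data.

## Interaction network

Edge i→j with weight w iff labeled user i wrote w comments under posts
authored by labeled user j, i ≠ j. Self-loops are excluded: commenting on
one's own post is not an inter-user interaction. Leanings are +1 (RSU) and
−1 (ASU); in/out neighbor averages are weight-weighted means, undefined for
users isolated in that direction; such users are excluded from the joint
distribution and counted. The joint histogram uses 21 bins per axis (odd,
so 0 is a bin center). In-neighbors of u are by definition the users
commenting on u's posts; because the opposite reading ("the authors u
attends to") is also natural, `joint_distribution(..., swap_directions=True)`
exchanges the axes rather than guessing.

## Synthetic generator

The generator emulates the study conditions, not open-domain text: 59.5% of
users on an alternative schedule; AEFI statements negative with probability
0.854 (ASU authors) and 0.748 (RSU authors); ~54% of profiles public; ~60%
of users with a resolvable state, census-proportional; per-user comment
counts Zipf with exponent 2.5 (mean ≈ 2 comments/user, heavy tail); posts
Poisson at 0.5 per user; schedule statements in 12% of comments and AEFI
statements in 8% — elevated relative to a whole-platform corpus because the
emulated corpus is already restricted to vaccine-topic threads and the
tests need label mass at moderate corpus sizes; 15% of alternative
statements phrased by negation; 10% of negative experiences second-hand;
ASU comment counts boosted 1.6× so alternative users are the more prolific
group, as observed. Timestamps span 2008-03-11 to 2019-04-26.

Sentences are realized from fixed template banks with controlled slots, so
every comment's ground-truth label is exact by construction. A `hard`
stratum (off by default, `hard_fraction`) injects decoys ("my work
schedule") and double-negation statements and flags them in the ground
truth, so easy and hard strata can be scored separately. Comment-to-post
attachment implements homophily h: with probability h the commenter picks a
post by a same-leaning author, otherwise any other author's post; h=1 gives
zero cross-leaning edges, h=0 recovers the population mixture.

All randomness flows through one NumPy generator keyed by `seed`, drawn in
a fixed order (leanings, states, profiles, posts, activity counts, then
comments), so equal seeds give byte-identical corpora.

**What passing tests do and do not show.** Perfect recovery on clean
template corpora demonstrates that the rule logic implements its
specification exactly — correct keyword/context gating, negation scope,
polarity flips, subject tables — not that the pipeline achieves any
particular accuracy on real forum text, whose paraphrase diversity,
sarcasm, typos and embedded quotations the templates deliberately do not
model. Real-corpus performance must be estimated with manual annotation via
`evaluation_metrics` / `cohen_kappa`.

## Numerical and statistical choices

- Wilson intervals via statsmodels; Pearson correlation via scipy on
  log-transformed pairs, zero-count states excluded and reported.
- The h=0 mixture check compares the mean in-neighbor leaning to
  2·(1−asu_fraction)−1 using a combined standard error
  (`network.mixture_calibration`): per-user spread plus the common-mode
  variance of the realized comment-weighted leaning mixture,
  √(Σc_i²·4p(1−p))/Σc_i. With heavy-tailed commenter activity the naive
  per-user SE is anti-conservative, because a few prolific commenters shift
  every user's in-average together.
- Test and acceptance problem sizes — 2,000 users for recovery, 800 for
  homophily, 2,000 null groups for screen calibration, 300 sampled tables
  (plus exhaustive N ≤ 14) for Fisher — are chosen so each suite gives
  stable statistics at interactive runtimes.

## Known limitations

- The shallow parser under-reaches on multi-clause sentences and reported
  speech; negation scope is clause-local by design.
- The lexicons reconstruct the published architecture with documented
  default lists; they are not a copy of any deployment's exact lists.
- The registrable-domain table covers common multi-part suffixes only.
- The generator's homophily acts on post selection, not thread depth; reply
  trees, temporal bursts and user churn are not modeled.
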