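# vaxforum

Rule-based detection of childhood vaccination-schedule adherence and
adverse-event (AEFI) experiences from parenting-forum comments.

## The problem

A non-negligible minority of parents delays or selects among recommended
childhood vaccines. On parenting forums these parents describe their
behaviour in their own words ("we do a delayed schedule", "I'm not following
the recommended schedule"), which makes forum corpora a large-scale,
unsolicited complement to surveys for studying vaccine hesitancy. `vaxforum`
is a reusable implementation of that analysis for epidemiologists and
computational social scientists:

1. **Schedule pipeline** — a high-precision filter + classifier over comment
   text. The filter matches schedule keywords inside syntactic patterns (the
   keyword must sit in a vaccination context: *I* (subject) *follow* (verb)
   *the regular* (adjective) *vaccination* (compound) *schedule* (keyword)),
   which rejects decoys like "my work schedule". The classifier labels a
   matched comment **recommended** by default and flips it to **alternative**
   when an alternative marker ("delayed", "selective", …) is matched or a
   negation attaches to the matched clause; a negated alternative marker
   flips twice.
2. **AEFI pipeline** — the same pattern machinery retrieves comments
   mentioning adverse events following immunization, labels them *negative
   experience* (a reaction attributed to the vaccine) or *positive
   experience* (attribution negated: "no reaction at all"), and resolves the
   experiencing subject (author / author's child / acquaintance) and the
   reaction type.
3. **User labeling** — comment labels aggregate to users (RSU =
   recommended-schedule user, ASU = alternative-schedule user; majority with
   latest-comment tie-break), with activity statistics (N_p, N_c, N_cs, the
   activity span τ) and the prolificacy curve: per class C_(a,b] of users'
   schedule-comment counts, the Wilson-interval probability that a comment is
   labeled recommended.
4. **Association screening** — all 2×2 machinery: odds ratios OR = ad/bc
   with Woolf CIs exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), Fisher exact screening,
   interest-group screens, URL-domain rankings, state geolocation with
   log-log Pearson correlation against census population, and evaluation
   metrics (filter precision, classifier sensitivity/specificity, Cohen's κ).
5. **Interaction network** — the directed weighted commenter→author graph
   with ±1 leanings and the joint distribution of weighted in/out-neighbor
   leanings, the echo-chamber diagnostic.
6. **Synthetic corpus generator** — template-realized corpora with exact
   per-comment and per-user ground truth and a tunable homophily parameter
   h, so every stage is testable without platform data.

## Worked example

```sh
vaxforum run-all --seed 8 --out run/     # simulates a 2000-user corpus
```

```
simulate: 997 posts, 5901 comments, 2000 profiles -> run/corpus
extract-schedule: 694 schedule-related comments
extract-aefi: 467 AEFI comments
label-users: 482 labeled users
associations: 7 groups retained, 10 domains, 40 states
network: 482 nodes, 641 edges
run-all complete -> run
```

Reading the funnel: of 5,901 comments, 694 carry schedule statements and 467
mention AEFI experiences; 482 distinct users get an RSU/ASU label; 7
interest groups are associated with one leaning at the 95% level; and the
interaction network over labeled users has 641 weighted commenter→author
edges. Equivalent library calls:

```python
from vaxforum import (SyntheticConfig, generate_corpus,
                      run_schedule_pipeline, ContingencyTable, odds_ratio_ci)

corpus, truth = generate_corpus(SyntheticConfig(n_users=2000, seed=8))
labels = run_schedule_pipeline(corpus)          # comment_id -> label

res = odds_ratio_ci(ContingencyTable(a=2086, b=356, c=1277, d=431))
print(f"OR={res.odds_ratio:.2f} CI=({res.ci_low:.2f}, {res.ci_high:.2f})")
# OR=1.98 CI=(1.69, 2.31)  — ASU vs RSU odds of a negative AEFI experience
```

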