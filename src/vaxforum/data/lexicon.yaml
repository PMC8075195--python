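# Default lexicon for the schedule-adherence extractor.
# All terms are lower-case lemmas; multiword markers are matched as
# consecutive lemma n-grams near the keyword.
schedule_keywords:
  - schedule
  - spacing
alternative_markers:
  - delayed
  - selective
  - alternative
  - alternate
  - modified
  - spread-out
  - spread out
  - one-at-a-time
  - one at a time
recommended_markers:
  - regular
  - recommended
  - normal
  - standard
  - routine
  - full
  - cdc
  - on time
negation_cues:
  - not
  - n't
  - never
  - "no"
# A keyword only counts as schedule-related when it occurs in a vaccination
# context: one of these terms as its compound/modifier, or elsewhere in the
# sentence when the keyword carries no competing compound (e.g. "work").
context_constraints:
  schedule: &vaxcontext
    - vaccination
    - vaccine
    - vaccinate
    - vax
    - immunization
    - immunize
    - shot
    - jab
    - dose
  spacing: *vaxcontext
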