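# Default vocabulary for the AEFI (adverse event following immunization)
# extractor: canonical reaction -> synonym lemmas (disjoint across canonicals).
# "reaction" itself is a canonical so bare attributions ("no reaction at all")
# are captured.
reactions:
  fever: [fever, feverish, temperature]
  seizure: [seizure, convulsion]
  developmental regression: [regression]
  pain: [pain, sore, soreness, ache]
  fussiness: [fussiness, fussy, cranky, irritable]
  rash: [rash, hives]
  swelling: [swelling, swell, lump]
  lethargy: [lethargy, lethargic, drowsy]
  vomiting: [vomit]
  reaction: [reaction, side effect]
# Immunization context terms: a reaction only counts when one of these occurs
# in the same sentence.
context_terms:
  - vaccine
  - vaccination
  - vaccinate
  - vax
  - shot
  - jab
  - dose
  - immunization
  - immunize
  - needle
  - mmr
  - dtap
  - booster
# Subject resolution tables (first-person child vs. wider circle).
child_terms: [son, daughter, baby, child, kid, toddler, infant, twin, newborn]
acquaintance_terms:
  - nephew
  - niece
  - cousin
  - friend
  - neighbor
  - coworker
  - sister
  - brother
  - mom
  - dad
  - grandma
  - grandpa
  - aunt
  - uncle
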