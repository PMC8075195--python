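"""Schedule-adherence extraction: filter + classifier.

The filter retrieves comments containing statements about the author's
vaccination-schedule behaviour by matching schedule keywords inside syntactic
patterns: the keyword must appear in a vaccination context (a context term as
its compound/modifier, or elsewhere in the sentence when the keyword carries
no competing compound — this is what rejects "my work schedule").

The classifier labels each retrieved comment ``recommended`` by default and
flips it to ``alternative`` when an alternative-schedule marker is matched
(e.g. "delayed", "selective") or when a negation attaches to the matched
clause ("I'm not following the recommended schedule").  A negated alternative
marker flips twice, back to recommended.  All alternative approaches
(delayed, selective, otherwise modified) are treated as one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional

import yaml

from vaxforum.corpus import Corpus, ForumComment
from vaxforum.parsing import SentenceSummary, find_keyword_hits, summarize_sentences

__all__ = [
    "Lexicon", "ScheduleMatch", "default_lexicon",
    "filter_schedule", "classify_schedule", "run_schedule_pipeline",
]

RECOMMENDED = "recommended"
ALTERNATIVE = "alternative"

# distance (in tokens) within which a bare marker lemma counts as a cue for
# a keyword even when modifier attachment did not chain it to the keyword
_CUE_WINDOW = 4


@dataclass(frozen=True)
class Lexicon:
    schedule_keywords: FrozenSet[str]
    alternative_markers: FrozenSet[str]
    recommended_markers: FrozenSet[str]
    negation_cues: FrozenSet[str]
    context_constraints: Mapping[str, FrozenSet[str]]

    def __post_init__(self):
        if self.alternative_markers & self.recommended_markers:
            raise ValueError(
                "alternative and recommended marker sets must be disjoint"
            )

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            schedule_keywords=frozenset(raw["schedule_keywords"]),
            alternative_markers=frozenset(raw["alternative_markers"]),
            recommended_markers=frozenset(raw["recommended_markers"]),
            negation_cues=frozenset(raw["negation_cues"]),
            context_constraints={
                k: frozenset(v) for k, v in raw["context_constraints"].items()
            },
        )


def default_lexicon() -> Lexicon:
    return Lexicon.from_yaml(Path(__file__).parent / "data" / "lexicon.yaml")


@dataclass(frozen=True)
class ScheduleMatch:
    comment_id: str
    sentence_index: int
    keyword: str
    pattern_id: str
    alternative_cues: FrozenSet[str]
    recommended_cues: FrozenSet[str]
    negated: bool

    @property
    def polarity_cues(self) -> FrozenSet[str]:
        return self.alternative_cues | self.recommended_cues


def _multiword_cues(lemmas: List[str], markers: FrozenSet[str]) -> FrozenSet[str]:
    """Match multiword markers ("spread out", "on time") as lemma n-grams."""
    found = set()
    multi = [m for m in markers if " " in m]
    for m in multi:
        parts = m.split()
        k = len(parts)
        for i in range(len(lemmas) - k + 1):
            if lemmas[i:i + k] == parts:
                found.add(m)
                break
    return frozenset(found)


def _window_cues(
    summary: SentenceSummary, kw_index: int, markers: FrozenSet[str]
) -> FrozenSet[str]:
    found = set()
    lo = max(0, kw_index - _CUE_WINDOW)
    hi = min(len(summary.lemmas), kw_index + _CUE_WINDOW + 1)
    for i in range(lo, hi):
        lemma = summary.lemmas[i]
        if lemma in markers:
            found.add(lemma)
        # hyphenated tokens carry their own lemma ("spread-out")
        dehyph = lemma.replace("-", " ")
        if dehyph in markers:
            found.add(dehyph)
    return frozenset(found)


def _clause_negated(summary: SentenceSummary, kw_index: int) -> bool:
    """A negation flips a match iff it attaches to the governing verb of the
    keyword's clause, or (determiner "no") directly to the keyword phrase."""
    for i in summary.negation_indices:
        lemma = summary.lemmas[i]
        if lemma == "no":
            if i < kw_index and summary.head_index[i] <= kw_index:
                return True
        elif summary.main_verb_index is not None:
            if summary.head_index[i] == summary.main_verb_index:
                return True
    return False


def match_sentence(
    summary: SentenceSummary, lexicon: Lexicon, comment_id: str, sentence_index: int
) -> List[ScheduleMatch]:
    """Apply the pattern table to one sentence summary."""
    matches = []
    hits = summary.keyword_hits or find_keyword_hits(
        summary, lexicon.schedule_keywords
    )
    sentence_lemmas = summary.lemma_set()
    for hit in hits:
        if hit.keyword not in lexicon.schedule_keywords:
            continue
        context = lexicon.context_constraints.get(hit.keyword, frozenset())
        mods = hit.adjectival_modifiers | hit.compound_modifiers
        if context & mods:
            pattern_id = "kw_context_modifier"
        else:
            competing = (
                hit.compound_modifiers - context
                - lexicon.alternative_markers - lexicon.recommended_markers
            )
            if competing:
                continue  # e.g. "work schedule": disambiguated away
            if context & sentence_lemmas:
                pattern_id = "kw_context_sentence"
            else:
                continue
        alt = (
            (lexicon.alternative_markers & mods)
            | _window_cues(summary, hit.token_index, lexicon.alternative_markers)
            | _multiword_cues(summary.lemmas, lexicon.alternative_markers)
        )
        rec = (
            (lexicon.recommended_markers & mods)
            | _window_cues(summary, hit.token_index, lexicon.recommended_markers)
            | _multiword_cues(summary.lemmas, lexicon.recommended_markers)
        )
        matches.append(ScheduleMatch(
            comment_id=comment_id,
            sentence_index=sentence_index,
            keyword=hit.keyword,
            pattern_id=pattern_id,
            alternative_cues=frozenset(alt),
            recommended_cues=frozenset(rec),
            negated=_clause_negated(summary, hit.token_index),
        ))
    return matches


def filter_schedule(comment: ForumComment, lexicon: Lexicon) -> List[ScheduleMatch]:
    """Retrieve schedule-statement matches from one comment.

    Empty list means the comment is not schedule-related.
    """
    matches = []
    for s_idx, summary in enumerate(
        summarize_sentences(comment.text, lexicon.schedule_keywords)
    ):
        matches.extend(match_sentence(summary, lexicon, comment.comment_id, s_idx))
    return matches


def _match_label(match: ScheduleMatch) -> str:
    if match.negated:
        # negated alternative cue flips twice; negated recommended (or bare)
        # statement means the author is not on the recommended schedule
        return RECOMMENDED if match.alternative_cues else ALTERNATIVE
    return ALTERNATIVE if match.alternative_cues else RECOMMENDED


def classify_schedule(matches: List[ScheduleMatch]) -> Optional[str]:
    """Label a comment from its matches; None iff no matches.

    Pure and permutation-invariant: conflicting sentence cues resolve
    alternative-over-recommended (alternative markers are the specific
    signal; recommended is only the default).
    """
    if not matches:
        return None
    labels = {_match_label(m) for m in matches}
    return ALTERNATIVE if ALTERNATIVE in labels else RECOMMENDED


def run_schedule_pipeline(
    corpus: Corpus, lexicon: Optional[Lexicon] = None
) -> Dict[str, str]:
    """Filter + classify every comment; returns comment_id -> label.

    Posts are deliberately not examined: post bodies are often speculative or
    questioning, while comments carry the author's own stated behaviour.
    """
    lexicon = lexicon or default_lexicon()
    out: Dict[str, str] = {}
    for comment in corpus.comments:
        label = classify_schedule(filter_schedule(comment, lexicon))
        if label is not None:
            out[comment.comment_id] = label
    return out
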