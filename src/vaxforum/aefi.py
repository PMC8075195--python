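"""Extraction of adverse-event-following-immunization (AEFI) experiences.

Re-uses the shallow-parse pattern machinery of the schedule pipeline: a
comment mentions an AEFI experience when a reaction term occurs in an
immunization context (a vaccine/shot term in the same sentence).  The
comment is a *negative experience* when the author attributes a reaction to
the vaccine ("My nephew always runs a high fever after shots"), and a
*positive experience* when every attribution is negated ("no reaction at
all after her shots").  Both first- and second-hand experiences count; the
experiencing subject (author / author's child / acquaintance) is resolved
from the subject noun phrase and reported as a separate field, never used
as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import yaml

from vaxforum.corpus import Corpus, ForumComment
from vaxforum.parsing import SentenceSummary, summarize_sentences

__all__ = [
    "AEFIMatch", "ReactionVocabulary", "default_vocabulary",
    "filter_aefi", "classify_experience", "resolve_subject",
    "run_aefi_pipeline",
]

NEGATIVE = "negative_experience"
POSITIVE = "positive_experience"

SUBJECT_AUTHOR = "author"
SUBJECT_CHILD = "child"
SUBJECT_ACQUAINTANCE = "acquaintance"
SUBJECT_UNKNOWN = "unknown"


@dataclass(frozen=True)
class ReactionVocabulary:
    """Canonical reaction -> synonym lemma sets, plus context/kinship tables."""

    terms: Mapping[str, FrozenSet[str]]
    context_terms: FrozenSet[str]
    child_terms: FrozenSet[str]
    acquaintance_terms: FrozenSet[str]

    def __post_init__(self):
        seen: Dict[str, str] = {}
        for canonical, syns in self.terms.items():
            for syn in syns:
                if syn in seen:
                    raise ValueError(
                        f"synonym {syn!r} appears under both "
                        f"{seen[syn]!r} and {canonical!r}"
                    )
                seen[syn] = canonical

    def synonym_index(self) -> Dict[str, str]:
        return {
            syn: canonical
            for canonical, syns in self.terms.items()
            for syn in syns
        }

    @classmethod
    def from_yaml(cls, path) -> "ReactionVocabulary":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            terms={k: frozenset(v) for k, v in raw["reactions"].items()},
            context_terms=frozenset(raw["context_terms"]),
            child_terms=frozenset(raw["child_terms"]),
            acquaintance_terms=frozenset(raw["acquaintance_terms"]),
        )


def default_vocabulary() -> ReactionVocabulary:
    return ReactionVocabulary.from_yaml(
        Path(__file__).parent / "data" / "reactions.yaml"
    )


@dataclass(frozen=True)
class AEFIMatch:
    comment_id: str
    sentence_index: int
    reaction_terms: FrozenSet[str]  # canonical reactions
    subject: str
    attribution_negated: bool


def _reaction_hits(
    summary: SentenceSummary, vocabulary: ReactionVocabulary
) -> List[Tuple[int, str]]:
    """(token index, canonical reaction) pairs, incl. multiword synonyms."""
    index = vocabulary.synonym_index()
    hits = []
    lemmas = summary.lemmas
    for i, lemma in enumerate(lemmas):
        if lemma in index:
            hits.append((i, index[lemma]))
    for syn, canonical in index.items():
        if " " not in syn:
            continue
        parts = syn.split()
        k = len(parts)
        for i in range(len(lemmas) - k + 1):
            if lemmas[i:i + k] == parts:
                hits.append((i, canonical))
    return hits


def _attribution_negated(summary: SentenceSummary, reaction_idx: int) -> bool:
    for i in summary.negation_indices:
        lemma = summary.lemmas[i]
        if lemma == "no":
            if i < reaction_idx and summary.head_index[i] <= reaction_idx:
                return True
        elif summary.main_verb_index is not None:
            if summary.head_index[i] == summary.main_verb_index:
                return True
    return False


def resolve_subject(summary: SentenceSummary, vocabulary: ReactionVocabulary) -> str:
    """Resolve who experienced the reaction from the subject noun phrase.

    author: first-person singular subject; child: a child-kinship head noun
    possessed by the first person; acquaintance: any other kinship/social
    term in the phrase (incl. "my friend's kid"); unknown otherwise.
    """
    lemmas = summary.subject_tokens()
    if not lemmas:
        return SUBJECT_UNKNOWN
    if any(l in vocabulary.acquaintance_terms for l in lemmas):
        return SUBJECT_ACQUAINTANCE
    head = lemmas[-1]
    if head in vocabulary.child_terms and lemmas[0] in ("my", "our"):
        return SUBJECT_CHILD
    if head == "i":
        return SUBJECT_AUTHOR
    return SUBJECT_UNKNOWN


def filter_aefi(
    comment: ForumComment, vocabulary: Optional[ReactionVocabulary] = None
) -> List[AEFIMatch]:
    """Retrieve AEFI-experience matches; empty list means unrelated."""
    vocabulary = vocabulary or default_vocabulary()
    matches = []
    for s_idx, summary in enumerate(summarize_sentences(comment.text)):
        if not (vocabulary.context_terms & summary.lemma_set()):
            continue
        hits = _reaction_hits(summary, vocabulary)
        if not hits:
            continue
        subject = resolve_subject(summary, vocabulary)
        # one match per sentence; a sentence asserting any non-negated
        # reaction is a non-negated attribution
        negated = all(_attribution_negated(summary, i) for i, _ in hits)
        matches.append(AEFIMatch(
            comment_id=comment.comment_id,
            sentence_index=s_idx,
            reaction_terms=frozenset(canonical for _, canonical in hits),
            subject=subject,
            attribution_negated=negated,
        ))
    return matches


def classify_experience(matches: List[AEFIMatch]) -> Optional[str]:
    """negative iff any non-negated attribution; positive iff all negated.

    Monotone: adding a non-negated match can only move none/positive to
    negative, never the reverse.
    """
    if not matches:
        return None
    if any(not m.attribution_negated for m in matches):
        return NEGATIVE
    return POSITIVE


def run_aefi_pipeline(
    corpus: Corpus, vocabulary: Optional[ReactionVocabulary] = None
) -> Dict[str, Tuple[str, str, FrozenSet[str]]]:
    """Map comment_id -> (experience label, subject, canonical reactions)."""
    vocabulary = vocabulary or default_vocabulary()
    out: Dict[str, Tuple[str, str, FrozenSet[str]]] = {}
    for comment in corpus.comments:
        matches = filter_aefi(comment, vocabulary)
        label = classify_experience(matches)
        if label is None:
            continue
        subject = next(
            (m.subject for m in matches if m.subject != SUBJECT_UNKNOWN),
            SUBJECT_UNKNOWN,
        )
        reactions: FrozenSet[str] = frozenset().union(
            *(m.reaction_terms for m in matches)
        )
        out[comment.comment_id] = (label, subject, reactions)
    return out
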