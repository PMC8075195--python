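"""Deterministic rule-based shallow parsing of comment text.

Both extraction pipelines operate on a structured per-sentence summary: the
grammatical subject, the main verb, which negation cues attach where, and —
for each keyword of interest — its adjectival and compound (noun-noun)
modifiers.  A full statistical dependency parse is unnecessary for this:
the summaries required by the pattern tables are recoverable from token-level
rules (closed word classes, a small lemmatizer, and left-attachment of
modifiers inside noun phrases), which also makes the pipeline fully
deterministic and dependency-free.

The parser is intentionally shallow: it does not attempt clause embedding,
coordination scope, or long-distance attachment.  Its contract is only that
the fields of :class:`SentenceSummary` are correct for the declarative,
single-clause sentence shapes the pattern tables target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Tuple

__all__ = ["KeywordHit", "SentenceSummary", "summarize_sentences", "find_keyword_hits"]

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[A-Za-z]+(?:-[A-Za-z]+)*(?:'[A-Za-z]+)?|\d+|[^\sA-Za-z\d]")

# Closed word classes.  These lists only need to cover the vocabulary the
# pattern tables and template banks draw from, plus common function words.
_PRONOUNS = {"i", "we", "you", "he", "she", "they", "it", "me", "us", "them"}
_POSSESSIVES = {"my", "our", "your", "his", "her", "their", "its"}
_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "any",
                "some", "each", "every", "no"} | _POSSESSIVES
_NEGATION_CUES = {"not", "n't", "never", "no"}
_PREPOSITIONS = {"on", "for", "to", "of", "in", "at", "with", "after",
                 "before", "about", "from", "by", "into", "over", "under",
                 "around", "during", "since", "until", "through", "without"}
_CONJUNCTIONS = {"and", "but", "or", "so", "because", "if", "when", "while",
                 "that", "than", "as"}
_ADVERBS = {"always", "usually", "often", "also", "still", "just", "really",
            "now", "again", "here", "there", "very", "too", "only", "even"}

_AUXILIARIES = {"be", "am", "is", "are", "was", "were", "been", "being",
                "do", "does", "did", "have", "has", "had", "will", "would",
                "can", "could", "may", "might", "must", "should", "shall"}

_VERB_LEMMAS = _AUXILIARIES | {
    "follow", "stick", "go", "get", "give", "receive", "take", "use",
    "choose", "opt", "decide", "plan", "keep", "stay", "put", "vaccinate",
    "vax", "immunize", "delay", "space", "spread", "skip", "refuse",
    "run", "react", "experience", "suffer", "develop", "happen", "occur",
    "seem", "say", "think", "know", "want", "feel", "see", "make", "come",
    "need", "try", "start", "break", "cry", "sleep", "eat", "swell",
    "vomit", "throw", "spike", "mention", "report", "tell", "hear",
    "notice", "handle", "tolerate", "love", "hate", "trust", "worry",
    "agree", "prefer", "switch", "wait",
}

# Adjective inventory for modifier classification; anything unlisted that a
# noun-phrase walk encounters is treated as a compound noun modifier unless
# a suffix heuristic says otherwise.
_ADJECTIVES = {
    "regular", "recommended", "normal", "full", "standard", "routine",
    "delayed", "selective", "alternative", "alternate", "modified",
    "spread-out", "crazy", "busy", "high", "low", "mild", "serious",
    "severe", "bad", "little", "big", "new", "old", "whole", "slight",
    "nasty", "awful", "terrible", "typical", "usual", "official", "same",
    "different", "first", "second", "next", "last", "own",
}
_ADJ_SUFFIXES = ("ive", "ous", "ful", "ble", "ical", "ish")

_LEMMA_EXCEPTIONS = {
    "is": "be", "are": "be", "am": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "doing": "do", "done": "do",
    "ran": "run", "runs": "run", "running": "run",
    "went": "go", "goes": "go", "going": "go", "gone": "go",
    "got": "get", "gets": "get", "getting": "get", "gotten": "get",
    "gave": "give", "given": "give", "giving": "give",
    "took": "take", "taken": "take", "taking": "take",
    "chose": "choose", "chosen": "choose",
    "said": "say", "says": "say",
    "thought": "think", "knew": "know", "felt": "feel", "saw": "see",
    "made": "make", "came": "come", "kept": "keep", "put": "put",
    "stuck": "stick", "broke": "break", "broken": "break",
    "threw": "throw", "thrown": "throw",
    "swollen": "swell", "swelled": "swell",
    "children": "child", "babies": "baby", "kids": "kid",
    "shots": "shot", "vaccines": "vaccine", "vaccinations": "vaccination",
    "vaxes": "vax", "jabs": "jab", "doses": "dose", "needles": "needle",
    "schedules": "schedule", "reactions": "reaction", "fevers": "fever",
    "swelling": "swelling", "swellings": "swelling",
    "seizures": "seizure", "rashes": "rash", "hives": "hives",
    "this": "this", "his": "his", "its": "its", "'s": "'s", "n't": "n't",
    "spacing": "spacing", "news": "news", "delayed": "delayed",
    "recommended": "recommended", "modified": "modified",
    "spread-out": "spread-out", "one-at-a-time": "one-at-a-time",
}

_KEEP_S = {"always", "perhaps", "us", "yes", "sometimes", "besides", "hives"}


def lemmatize(token: str) -> str:
    """Lower-case and strip common English inflection from one token."""
    w = token.lower()
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if w in _KEEP_S or len(w) <= 3:
        return w
    if w.endswith("ies"):
        return w[:-3] + "y"
    if w.endswith(("ches", "shes", "sses", "xes", "zes")):
        return w[:-2]
    if w.endswith("ss") or w.endswith("us"):
        return w
    if w.endswith("s") and not w.endswith("'s"):
        return w[:-1]
    if w.endswith("ing") and len(w) > 5:
        stem = w[:-3]
        if stem.endswith(("at", "iz", "us", "ac")):
            return stem + "e"
        if len(stem) > 2 and stem[-1] == stem[-2]:
            return stem[:-1]
        return stem
    if w.endswith("ed") and len(w) > 4:
        stem = w[:-2]
        if stem.endswith(("at", "iz", "us", "ac")):
            return stem + "e"
        if len(stem) > 2 and stem[-1] == stem[-2]:
            return stem[:-1]
        return stem
    return w


@dataclass(frozen=True)
class KeywordHit:
    keyword: str
    token_index: int
    adjectival_modifiers: FrozenSet[str]
    compound_modifiers: FrozenSet[str]


@dataclass
class SentenceSummary:
    """Structured summary of one sentence.

    ``head_index`` and ``dep_relation`` give one governor and relation label
    per token: noun-phrase modifiers attach to their head noun, negation cues
    to the verb (or following noun for determiner "no"), and everything else
    to the main verb.
    """

    tokens: List[str]
    lemmas: List[str]
    head_index: List[int]
    dep_relation: List[str]
    subject_span: Optional[Tuple[int, int]]
    main_verb_index: Optional[int]
    negation_indices: List[int]
    keyword_hits: List[KeywordHit] = field(default_factory=list)

    def lemma_set(self) -> FrozenSet[str]:
        return frozenset(self.lemmas)

    def subject_tokens(self) -> List[str]:
        if self.subject_span is None:
            return []
        a, b = self.subject_span
        return self.lemmas[a:b]


def _is_adjective(lemma: str, token: str) -> bool:
    if lemma in _ADJECTIVES or token.lower() in _ADJECTIVES:
        return True
    return token.lower().endswith(_ADJ_SUFFIXES)


def _find_main_verb(tokens: List[str], lemmas: List[str]) -> Optional[int]:
    candidates = []
    for i, lemma in enumerate(lemmas):
        if lemma not in _VERB_LEMMAS:
            continue
        # A "verb" directly after a determiner/possessive is a noun in
        # disguise ("my work schedule", "the spread of doses").
        if i > 0 and lemmas[i - 1] in _DETERMINERS:
            continue
        candidates.append(i)
    if not candidates:
        return None
    for i in candidates:
        if lemmas[i] not in _AUXILIARIES:
            return i
    return candidates[0]


def _find_subject(lemmas: List[str], verb_idx: Optional[int]) -> Optional[Tuple[int, int]]:
    end = verb_idx if verb_idx is not None else len(lemmas)
    # Nearest noun-phrase-like run before the verb, skipping adverbs such as
    # "always" sitting between subject and verb.
    i = end - 1
    while i >= 0 and (
        not lemmas[i].isalpha()
        or lemmas[i] in _NEGATION_CUES
        or lemmas[i] in _ADVERBS
        or lemmas[i] in _AUXILIARIES
        or lemmas[i] in _PREPOSITIONS
    ):
        i -= 1
    if i < 0:
        return None
    hi = i + 1
    lo = i
    while lo - 1 >= 0 and (
        lemmas[lo - 1] in _DETERMINERS
        or lemmas[lo - 1] == "'s"
        or (lemmas[lo - 1].isalpha() and lemmas[lo - 1] not in _VERB_LEMMAS
            and lemmas[lo - 1] not in _NEGATION_CUES)
    ):
        lo -= 1
    if lo >= hi:
        return None
    return (lo, hi)


def _summarize_one(raw: str) -> SentenceSummary:
    tokens = _TOKEN.findall(raw)
    # split clitic negation: "didn't" tokenizes as "didn't" -> did + n't
    split_tokens: List[str] = []
    for tok in tokens:
        low = tok.lower()
        if low.endswith("n't") and len(tok) > 3:
            split_tokens.extend([tok[:-3], "n't"])
        elif low.endswith("'s") and len(tok) > 2:
            split_tokens.extend([tok[:-2], "'s"])
        else:
            split_tokens.append(tok)
    tokens = split_tokens
    lemmas = [lemmatize(t) for t in tokens]
    n = len(tokens)

    verb_idx = _find_main_verb(tokens, lemmas)
    subject = _find_subject(lemmas, verb_idx)

    head = list(range(n))
    rel = ["dep"] * n
    root = verb_idx if verb_idx is not None else 0
    for i in range(n):
        head[i] = root
    if verb_idx is not None:
        rel[verb_idx] = "root"
        head[verb_idx] = verb_idx

    negations = []
    for i, lemma in enumerate(lemmas):
        if lemma not in _NEGATION_CUES:
            continue
        negations.append(i)
        rel[i] = "neg"
        if lemma == "no":
            # determiner "no": attach to the next content word
            j = i + 1
            while j < n and lemmas[j] in _DETERMINERS:
                j += 1
            head[i] = j if j < n else i
        elif verb_idx is not None:
            head[i] = verb_idx

    # noun-phrase internal attachment: adjectives and compound nouns attach
    # leftward onto the nearest following noun-ish token
    for i in range(n - 1):
        li, ti = lemmas[i], tokens[i]
        if li in _DETERMINERS and li != "no":
            rel[i] = "det"
            head[i] = i + 1
        elif (
            ti.isalpha()
            and li not in _PRONOUNS
            and li not in _NEGATION_CUES
            and li not in _PREPOSITIONS
            and li not in _CONJUNCTIONS
            and li not in _ADVERBS
            and i != verb_idx
            and lemmas[i + 1] not in _VERB_LEMMAS
            and tokens[i + 1].isalpha()
            and lemmas[i + 1] not in _PRONOUNS
            and lemmas[i + 1] not in _PREPOSITIONS
            and lemmas[i + 1] not in _CONJUNCTIONS
        ):
            if _is_adjective(li, ti):
                rel[i] = "amod"
            elif li not in _VERB_LEMMAS:
                rel[i] = "compound"
            if rel[i] in ("amod", "compound"):
                head[i] = i + 1

    if subject is not None:
        lo, hi = subject
        rel[hi - 1] = "nsubj"
        if verb_idx is not None:
            head[hi - 1] = verb_idx

    return SentenceSummary(
        tokens=tokens,
        lemmas=lemmas,
        head_index=head,
        dep_relation=rel,
        subject_span=subject,
        main_verb_index=verb_idx,
        negation_indices=negations,
    )


def summarize_sentences(text: str, keywords: FrozenSet[str] = frozenset()) -> List[SentenceSummary]:
    """Split ``text`` into sentences and build one summary per sentence.

    ``keywords`` (lower-case lemmas) populate ``keyword_hits`` with modifier
    attachments; pass the lexicon's keyword set or leave empty and call
    :func:`find_keyword_hits` later.
    """
    text = text.strip()
    if not text:
        return []
    summaries = []
    for raw in _SENT_SPLIT.split(text):
        if not raw.strip():
            continue
        summary = _summarize_one(raw)
        if not summary.tokens:
            continue
        if keywords:
            summary.keyword_hits = find_keyword_hits(summary, keywords)
        summaries.append(summary)
    return summaries


def find_keyword_hits(summary: SentenceSummary, keywords: FrozenSet[str]) -> List[KeywordHit]:
    """Locate keyword tokens and collect their noun-phrase modifiers.

    Modifiers are the contiguous run of amod/compound tokens whose attachment
    chain ends at the keyword token.
    """
    hits = []
    for i, lemma in enumerate(summary.lemmas):
        if lemma not in keywords:
            continue
        adj, comp = set(), set()
        j = i - 1
        while j >= 0 and summary.dep_relation[j] in ("amod", "compound", "det"):
            if summary.dep_relation[j] == "amod":
                adj.add(summary.lemmas[j])
            elif summary.dep_relation[j] == "compound":
                comp.add(summary.lemmas[j])
            j -= 1
        hits.append(KeywordHit(
            keyword=lemma,
            token_index=i,
            adjectival_modifiers=frozenset(adj),
            compound_modifiers=frozenset(comp),
        ))
    return hits
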