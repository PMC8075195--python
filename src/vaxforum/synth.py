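"""Synthetic forum-corpus generator with exact ground truth.

Emulates the statistical structure of a vaccine-topic parenting-forum
corpus — heavy-tailed per-user activity, schedule-adherence statements in
recommended / alternative / negated / decoy variants, AEFI-experience
statements with subject and reaction slots, leaning-correlated group
memberships, embedded URLs, self-reported locations, and a commenter-to-
author interaction structure with a tunable homophily parameter — while
recording the generating label of every comment and user.

Sentences are realized from template banks with controlled slots rather
than free generation, so the ground truth is exact by construction: the
artifact under test is the rule logic, not open-domain language
understanding.  All stochastic choices draw from one NumPy generator keyed
by ``seed``, in a fixed documented order (users, states, profiles, posts,
activity, then comments), so equal seeds give identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from datetime import datetime, timedelta, timezone
from typing import Dict, List, Mapping, Optional, Set, Tuple

import json
import numpy as np

from vaxforum.corpus import Corpus, ForumComment, ForumPost, UserProfile
from vaxforum.associations import state_populations

__all__ = ["SyntheticConfig", "GroundTruth", "generate_corpus", "realize_sentence"]

_EPOCH_START = datetime(2008, 3, 11, tzinfo=timezone.utc)
_EPOCH_END = datetime(2019, 4, 26, tzinfo=timezone.utc)

# ---------------------------------------------------------------------------
# Template banks.  Every template is guaranteed, by construction, to carry
# its intended ground-truth label under correct rule application.

_SCHEDULE_RECOMMENDED = [
    "I follow the regular vaccination schedule.",
    "We stick to the recommended vaccination schedule.",
    "We are vaccinating on the normal schedule.",
    "My son gets his shots on the recommended schedule.",
    "We are doing the full vaccination schedule.",
    "Our pediatrician keeps us on the standard vaccination schedule.",
]

_SCHEDULE_ALTERNATIVE = [
    "We do a delayed vaccination schedule.",
    "I put my kids on a selective schedule for shots.",
    "We follow an alternative vaccination schedule.",
    "We chose a modified schedule for her vaccines.",
    "I am doing a spread-out schedule for his shots.",
    "We vaccinate on a delayed schedule.",
]

# single negation of a recommended-marker statement -> alternative
_SCHEDULE_NEGATED_RECOMMENDED = [
    "I am not following the recommended vaccination schedule.",
    "We are not vaccinating on the regular schedule.",
    "We do not follow the normal schedule for vaccines.",
]

# double flip: negated alternative marker -> recommended (hard stratum)
_SCHEDULE_NEGATED_ALTERNATIVE = [
    "We are not doing a delayed schedule for her shots.",
    "I am not following a selective vaccination schedule.",
]

# decoys: the keyword without vaccination context (hard stratum, label none)
_SCHEDULE_DECOY = [
    "My work schedule is crazy this week.",
    "The bus schedule changed again.",
    "My sleep schedule is a mess with the new baby.",
    "Trying to get our feeding schedule on track.",
]

_AEFI_NEGATIVE = {
    "author": [
        "I ran a {reaction_phrase} after my flu shot.",
        "I was {reaction_adj} for two days after that vaccine.",
        "I got a {reaction_phrase} after my last booster.",
    ],
    "child": [
        "My daughter had a {reaction_phrase} after her shots.",
        "My son ran a {reaction_phrase} after his vaccines.",
        "My baby was {reaction_adj} all night after her shots.",
        "My toddler got a {reaction_phrase} after the MMR vaccine.",
    ],
    "acquaintance": [
        "My nephew always runs a {reaction_phrase} after shots.",
        "My friend's kid had a {reaction_phrase} after his vaccines.",
        "My niece got a {reaction_phrase} after her shots.",
        "My nephew was {reaction_adj} for days after his shots.",
    ],
}

_AEFI_POSITIVE = {
    "author": ["I never had a reaction to any vaccine."],
    "child": [
        "My son had no reaction to his shots.",
        "My daughter never had a fever after her vaccines.",
    ],
    "unknown": [
        "No reaction at all after her 2-month shots.",
        "There was no fever after the vaccine this time.",
    ],
}

# canonical reaction -> (noun phrase, adjectival form)
_REACTION_FORMS = {
    "fever": ("high fever", "feverish"),
    "seizure": ("seizure", None),
    "developmental regression": ("regression", None),
    "pain": ("lot of pain", "sore"),
    "fussiness": (None, "fussy"),
    "rash": ("rash", None),
    "swelling": ("swelling", None),
    "lethargy": (None, "lethargic"),
    "vomiting": (None, None),  # realized via "was vomiting"
}

_FILLER = [
    "Thanks for sharing, this is really helpful.",
    "Congrats on the new baby!",
    "Following this thread.",
    "Hang in there mama, it gets better.",
    "Anyone have tips for a good pediatrician in the area?",
    "We just moved and are still settling in.",
    "That sounds exhausting, hope you get some rest soon.",
]

_DOMAINS_SHARED = ["cdc.gov", "ncbi.nlm.nih.gov", "fda.gov", "community.babycenter.com"]
_DOMAINS_RSU = ["pediatrics.aappublications.org", "sciencebasedmedicine.org", "chop.edu"]
_DOMAINS_ASU = ["nvic.org", "askdrsears.com", "mercola.com"]

# per-leaning reaction sampling weights: ASUs skew toward serious reactions,
# RSUs toward common ones, mirroring the association structure under study
_REACTIONS = list(_REACTION_FORMS)
_REACTION_WEIGHTS = {
    "RSU": np.array([0.35, 0.02, 0.01, 0.2, 0.18, 0.1, 0.06, 0.05, 0.03]),
    "ASU": np.array([0.22, 0.12, 0.08, 0.12, 0.1, 0.12, 0.08, 0.08, 0.08]),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for a synthetic corpus.

    Defaults emulate the marginals of the study system: ~59.5% of
    schedule-labeled users on an alternative schedule, AEFI comments
    negative for ~85% of ASU and ~75% of RSU authors, heavy-tailed
    per-user comment counts, and about half of profiles public.
    """

    n_users: int = 2000
    asu_fraction: float = 0.595
    schedule_statement_rate: float = 0.12
    negation_rate: float = 0.15
    aefi_rate: float = 0.08
    aefi_negative_given_asu: float = 0.854
    aefi_negative_given_rsu: float = 0.748
    secondhand_rate: float = 0.1
    activity_exponent: float = 2.5
    homophily: float = 0.5
    n_groups: int = 20
    group_association_strength: float = 0.7
    url_rate: float = 0.05
    state_assignment: Optional[Mapping[str, float]] = None
    seed: int = 0
    hard_fraction: float = 0.0
    asu_prolificacy_boost: float = 1.6
    post_rate: float = 0.5
    public_profile_rate: float = 0.54
    location_rate: float = 0.6

    def validate(self) -> None:
        bad = []
        for name in (
            "asu_fraction", "schedule_statement_rate", "negation_rate",
            "aefi_rate", "aefi_negative_given_asu", "aefi_negative_given_rsu",
            "secondhand_rate", "homophily", "url_rate", "hard_fraction",
            "public_profile_rate", "location_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(name)
        if self.n_users < 2:
            bad.append("n_users")
        if self.schedule_statement_rate + self.aefi_rate > 1.0:
            bad.append("schedule_statement_rate+aefi_rate")
        if self.activity_exponent <= 1.0:
            bad.append("activity_exponent")
        if self.asu_prolificacy_boost <= 0:
            bad.append("asu_prolificacy_boost")
        if bad:
            raise ValueError(f"invalid SyntheticConfig fields: {', '.join(bad)}")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generating labels: exact by construction, keyed by comment/user id."""

    comment_schedule_label: Dict[str, str] = field(default_factory=dict)
    comment_aefi_label: Dict[str, str] = field(default_factory=dict)
    comment_subject: Dict[str, str] = field(default_factory=dict)
    comment_reaction: Dict[str, str] = field(default_factory=dict)
    user_schedule_label: Dict[str, str] = field(default_factory=dict)
    user_state: Dict[str, str] = field(default_factory=dict)
    hard_comments: Set[str] = field(default_factory=set)

    def schedule_label(self, comment_id: str) -> str:
        return self.comment_schedule_label.get(comment_id, "none")

    def aefi_label(self, comment_id: str) -> str:
        return self.comment_aefi_label.get(comment_id, "none")

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for uid, label in self.user_schedule_label.items():
                rec = {"kind": "user", "user_id": uid, "schedule_label": label,
                       "state": self.user_state.get(uid)}
                fh.write(json.dumps(rec) + "\n")
            cids = (set(self.comment_schedule_label)
                    | set(self.comment_aefi_label) | self.hard_comments)
            for cid in sorted(cids):
                rec = {
                    "kind": "comment", "comment_id": cid,
                    "schedule_label": self.schedule_label(cid),
                    "aefi_label": self.aefi_label(cid),
                    "subject": self.comment_subject.get(cid, "none"),
                    "reaction": self.comment_reaction.get(cid, "none"),
                    "hard": cid in self.hard_comments,
                }
                fh.write(json.dumps(rec) + "\n")


def realize_sentence(template_class: Tuple, slots: Dict, rng: np.random.Generator) -> str:
    """Realize one sentence from the template bank.

    ``template_class`` is a label tuple, e.g. ``("schedule", "recommended",
    "plain")`` or ``("aefi", "negative", "acquaintance")``; ``slots`` may
    carry a ``reaction`` canonical term.  Raises for unknown classes.
    """
    kind = template_class[0]
    if kind == "filler":
        return str(rng.choice(_FILLER))
    if kind == "schedule":
        _, label, variant = template_class
        bank = {
            ("recommended", "plain"): _SCHEDULE_RECOMMENDED,
            ("alternative", "plain"): _SCHEDULE_ALTERNATIVE,
            ("alternative", "negated"): _SCHEDULE_NEGATED_RECOMMENDED,
            ("recommended", "negated_alt"): _SCHEDULE_NEGATED_ALTERNATIVE,
            ("decoy", "plain"): _SCHEDULE_DECOY,
        }.get((label, variant))
        if bank is None:
            raise ValueError(f"unknown schedule template class: {template_class}")
        return str(rng.choice(bank))
    if kind == "aefi":
        _, polarity, subject = template_class
        if polarity == "positive":
            bank = _AEFI_POSITIVE.get(subject)
            if bank is None:
                raise ValueError(f"unknown AEFI template class: {template_class}")
            return str(rng.choice(bank))
        if polarity == "negative":
            bank = _AEFI_NEGATIVE.get(subject)
            if bank is None:
                raise ValueError(f"unknown AEFI template class: {template_class}")
            reaction = slots.get("reaction", "fever")
            noun, adj = _REACTION_FORMS.get(reaction, (reaction, None))
            if reaction == "vomiting":
                subj = {"author": "I was", "child": "My son was",
                        "acquaintance": "My nephew was"}[subject]
                return f"{subj} vomiting all night after the shots."
            candidates = []
            for tpl in bank:
                if "{reaction_phrase}" in tpl and noun is not None:
                    candidates.append(tpl.format(reaction_phrase=noun))
                elif "{reaction_adj}" in tpl and adj is not None:
                    candidates.append(tpl.format(reaction_adj=adj))
            if not candidates:
                raise ValueError(
                    f"no template realizes reaction {reaction!r} for {subject!r}"
                )
            return str(rng.choice(candidates))
    raise ValueError(f"unknown template class: {template_class}")


def _random_timestamp(rng: np.random.Generator) -> datetime:
    span = int((_EPOCH_END - _EPOCH_START).total_seconds())
    return _EPOCH_START + timedelta(seconds=int(rng.integers(0, span)))


def _pick_url(leaning: str, rng: np.random.Generator) -> str:
    if rng.random() < 0.6:
        domain = str(rng.choice(_DOMAINS_SHARED))
    else:
        domain = str(rng.choice(_DOMAINS_RSU if leaning == "RSU" else _DOMAINS_ASU))
    return f"More info here: https://www.{domain}/article"


def generate_corpus(config: SyntheticConfig) -> Tuple[Corpus, GroundTruth]:
    """Generate a corpus with exact ground truth; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    user_ids = [f"u{i:05d}" for i in range(n)]
    truth = GroundTruth()

    # 1. leanings
    is_asu = rng.random(n) < config.asu_fraction
    for uid, asu in zip(user_ids, is_asu):
        truth.user_schedule_label[uid] = "ASU" if asu else "RSU"

    # 2. states
    if config.state_assignment is not None:
        state_names = list(config.state_assignment)
        weights = np.array([config.state_assignment[s] for s in state_names], float)
    else:
        pops = state_populations()
        state_names = list(pops)
        weights = np.array([pops[s] for s in state_names], float)
    weights = weights / weights.sum()
    for uid in user_ids:
        if rng.random() < config.location_rate:
            truth.user_state[uid] = str(rng.choice(state_names, p=weights))

    # 3. profiles and groups
    n_assoc = config.n_groups // 2
    group_names = [f"Thematic Circle {g:02d}" for g in range(config.n_groups)]
    group_affinity = {
        group_names[g]: ("ASU" if g % 2 == 0 else "RSU")
        for g in range(n_assoc)
    }
    base_join = 0.05
    profiles = []
    local_group_members: Dict[str, str] = {}
    for i, uid in enumerate(user_ids):
        public = bool(rng.random() < config.public_profile_rate)
        if not public:
            profiles.append(UserProfile(uid, None, frozenset(), public=False))
            continue
        groups = set()
        leaning = truth.user_schedule_label[uid]
        for g in group_names:
            affinity = group_affinity.get(g)
            p = base_join * (1 + 3 * config.group_association_strength) \
                if affinity == leaning else base_join
            if rng.random() < p:
                groups.add(g)
        state = truth.user_state.get(uid)
        location = None
        if state is not None:
            # half self-report, half only discoverable via a local group
            if rng.random() < 0.5:
                location = state
            else:
                groups.add(f"{state} Moms")
                local_group_members[uid] = state
        profiles.append(UserProfile(uid, location, frozenset(groups), public=True))

    # 4. posts
    post_counts = rng.poisson(config.post_rate, size=n)
    posts: List[ForumPost] = []
    for i, uid in enumerate(user_ids):
        for _ in range(int(post_counts[i])):
            posts.append(ForumPost(
                post_id=f"p{len(posts):06d}",
                user_id=uid,
                timestamp=_random_timestamp(rng),
                title="Question about vaccines",
                body="Looking for experiences from other parents.",
            ))
    if not posts:
        posts.append(ForumPost(
            "p000000", user_ids[0], _random_timestamp(rng),
            "Question about vaccines", "Looking for experiences.",
        ))
    posts_by_leaning: Dict[str, List[int]] = {"RSU": [], "ASU": []}
    for idx, post in enumerate(posts):
        posts_by_leaning[truth.user_schedule_label[post.user_id]].append(idx)

    # 5. heavy-tailed activity
    counts = np.minimum(rng.zipf(config.activity_exponent, size=n), 500)
    boosted = np.where(
        is_asu, np.maximum(1, np.round(counts * config.asu_prolificacy_boost)), counts
    ).astype(int)

    # 6. comments
    comments: List[ForumComment] = []
    own_posts: Dict[str, List[int]] = {}
    for idx, post in enumerate(posts):
        own_posts.setdefault(post.user_id, []).append(idx)
    all_post_indices = np.arange(len(posts))
    for i, uid in enumerate(user_ids):
        leaning = truth.user_schedule_label[uid]
        own = set(own_posts.get(uid, ()))
        same = [j for j in posts_by_leaning[leaning] if j not in own]
        others = [j for j in all_post_indices if j not in own]
        for _ in range(int(boosted[i])):
            # homophily: with prob h attach to a same-leaning author's post,
            # otherwise to any other author's post
            if rng.random() < config.homophily:
                pool = same or (own_posts.get(uid) if config.homophily == 1.0 else others) or others
            else:
                pool = others or list(all_post_indices)
            if not pool:
                pool = list(all_post_indices)
            post = posts[int(rng.choice(pool))]
            cid = f"c{len(comments):07d}"
            r = rng.random()
            hard_roll = rng.random() < config.hard_fraction
            if r < config.schedule_statement_rate:
                if leaning == "RSU":
                    if hard_roll:
                        cls = ("schedule", "recommended", "negated_alt")
                        truth.hard_comments.add(cid)
                    else:
                        cls = ("schedule", "recommended", "plain")
                    truth.comment_schedule_label[cid] = "recommended"
                else:
                    if rng.random() < config.negation_rate:
                        cls = ("schedule", "alternative", "negated")
                    else:
                        cls = ("schedule", "alternative", "plain")
                    truth.comment_schedule_label[cid] = "alternative"
                text = realize_sentence(cls, {}, rng)
            elif r < config.schedule_statement_rate + config.aefi_rate:
                p_neg = (config.aefi_negative_given_asu if leaning == "ASU"
                         else config.aefi_negative_given_rsu)
                if rng.random() < p_neg:
                    if rng.random() < config.secondhand_rate:
                        subject = "acquaintance"
                    else:
                        subject = "author" if rng.random() < 0.5 else "child"
                    reaction = str(rng.choice(
                        _REACTIONS, p=_REACTION_WEIGHTS[leaning]
                        / _REACTION_WEIGHTS[leaning].sum()
                    ))
                    text = realize_sentence(
                        ("aefi", "negative", subject), {"reaction": reaction}, rng
                    )
                    truth.comment_aefi_label[cid] = "negative"
                    truth.comment_subject[cid] = subject
                    truth.comment_reaction[cid] = reaction
                else:
                    subject = str(rng.choice(["author", "child", "unknown"]))
                    text = realize_sentence(("aefi", "positive", subject), {}, rng)
                    truth.comment_aefi_label[cid] = "positive"
                    truth.comment_subject[cid] = (
                        subject if subject != "unknown" else "none"
                    )
            else:
                if hard_roll:
                    text = realize_sentence(("schedule", "decoy", "plain"), {}, rng)
                    truth.hard_comments.add(cid)
                else:
                    text = realize_sentence(("filler",), {}, rng)
            if rng.random() < config.url_rate:
                text = f"{text} {_pick_url(leaning, rng)}"
            comments.append(ForumComment(
                comment_id=cid,
                post_id=post.post_id,
                user_id=uid,
                timestamp=_random_timestamp(rng),
                text=text,
            ))

    corpus = Corpus(posts=posts, comments=comments, profiles=profiles)
    return corpus, truth
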