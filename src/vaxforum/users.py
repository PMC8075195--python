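"""User-level aggregation of comment labels and activity statistics.

Users with at least one schedule-related comment are classified as RSU
(recommended-schedule user) or ASU (alternative-schedule user) by propagating
their comment labels: unanimous labels propagate directly, discordant labels
resolve by majority, and an exact tie resolves to the chronologically latest
comment's label.  The conflict rule is injectable so alternatives (e.g.
any-alternative-wins) can be configured.

Users with at least one AEFI-labeled comment are classified as *reporting
negative experiences* iff any of their comments is a negative experience.

The prolificacy curve bins schedule-related comments into classes C_(a,b] by
their author's schedule-comment count and estimates, per class, the
probability (with Wilson 95% CI) that a comment is labeled recommended.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from statsmodels.stats.proportion import proportion_confint

from vaxforum.corpus import Corpus

__all__ = [
    "UserScheduleLabel", "UserExperienceLabel", "ActivityStats",
    "ProlificacyClass", "aggregate_schedule_labels",
    "aggregate_experience_labels", "compute_activity", "prolificacy_curve",
    "label_all_users", "RSU", "ASU",
]

RSU = "RSU"
ASU = "ASU"

DEFAULT_CLASS_BOUNDS: Tuple[float, ...] = (0, 1, 2, 4, 8, float("inf"))


@dataclass(frozen=True)
class UserScheduleLabel:
    user_id: str
    value: str  # RSU | ASU
    n_schedule_comments: int
    conflict_resolved: bool


@dataclass(frozen=True)
class UserExperienceLabel:
    user_id: str
    value: str  # reporting_negative | reporting_positive


@dataclass(frozen=True)
class ActivityStats:
    user_id: str
    n_posts: int
    n_comments: int
    n_schedule_comments: int
    tau: int  # days between first and last comment
    single_day: bool  # excluded from tau summaries
    comments_received_per_post: List[int]  # per authored post


def majority_latest_rule(labeled: Sequence[Tuple[str, datetime]]) -> str:
    """Majority vote; an exact tie resolves to the latest comment's label."""
    counts: Dict[str, int] = {}
    for label, _ in labeled:
        counts[label] = counts.get(label, 0) + 1
    best = max(counts.values())
    winners = [l for l, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0]
    return max(labeled, key=lambda pair: pair[1])[0]


def aggregate_schedule_labels(
    labeled_comments: Sequence[Tuple[str, datetime]],
    user_id: str = "",
    rule: Callable[[Sequence[Tuple[str, datetime]]], str] = majority_latest_rule,
) -> UserScheduleLabel:
    """Collapse a user's (comment label, timestamp) pairs into RSU/ASU."""
    if not labeled_comments:
        raise ValueError("cannot aggregate zero labeled comments")
    labels = {label for label, _ in labeled_comments}
    if len(labels) == 1:
        winner = next(iter(labels))
        conflict = False
    else:
        winner = rule(labeled_comments)
        conflict = True
    return UserScheduleLabel(
        user_id=user_id,
        value=ASU if winner == "alternative" else RSU,
        n_schedule_comments=len(labeled_comments),
        conflict_resolved=conflict,
    )


def aggregate_experience_labels(
    labels: Sequence[str], user_id: str = ""
) -> UserExperienceLabel:
    """reporting_negative iff any comment is a negative experience."""
    if not labels:
        raise ValueError("cannot aggregate zero labeled comments")
    value = (
        "reporting_negative"
        if "negative_experience" in labels
        else "reporting_positive"
    )
    return UserExperienceLabel(user_id=user_id, value=value)


def compute_activity(
    corpus: Corpus,
    user_id: str,
    schedule_labels: Optional[Dict[str, str]] = None,
) -> ActivityStats:
    """Per-user activity: N_p, N_c, N_cs, tau, and replies received per post.

    tau is the whole-day span between the user's first and last comment;
    users whose comments all fall on a single day are flagged so summaries
    can exclude them.  Replies received counts comments (by anyone) under
    each post the user authored.
    """
    comments = [c for c in corpus.comments if c.user_id == user_id]
    posts = [p for p in corpus.posts if p.user_id == user_id]
    if not comments and not posts:
        raise KeyError(f"unknown user: {user_id}")
    if comments:
        times = sorted(c.timestamp for c in comments)
        tau = (times[-1].date() - times[0].date()).days
    else:
        tau = 0
    schedule_labels = schedule_labels or {}
    n_cs = sum(1 for c in comments if c.comment_id in schedule_labels)
    own_posts = {p.post_id for p in posts}
    received: Dict[str, int] = {pid: 0 for pid in own_posts}
    for c in corpus.comments:
        if c.post_id in own_posts:
            received[c.post_id] += 1
    return ActivityStats(
        user_id=user_id,
        n_posts=len(posts),
        n_comments=len(comments),
        n_schedule_comments=n_cs,
        tau=tau,
        single_day=tau == 0,
        comments_received_per_post=sorted(received.values()),
    )


@dataclass(frozen=True)
class ProlificacyClass:
    a: float
    b: float
    n: int
    k: int  # comments labeled recommended
    p_hat: float
    ci_low: float
    ci_high: float


def prolificacy_curve(
    comment_labels: Dict[str, str],
    comment_authors: Dict[str, str],
    bounds: Sequence[float] = DEFAULT_CLASS_BOUNDS,
    alpha: float = 0.05,
) -> List[ProlificacyClass]:
    """Per-class probability that a schedule-related comment is recommended.

    A comment belongs to class C_(a,b] when its author wrote a number of
    schedule-related comments in (a, b].  Empty classes are omitted; the
    classes partition the labeled comments.
    """
    bounds = list(bounds)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("class bounds must be strictly increasing")
    per_user: Dict[str, int] = {}
    for cid in comment_labels:
        user = comment_authors[cid]
        per_user[user] = per_user.get(user, 0) + 1
    classes = []
    for a, b in zip(bounds, bounds[1:]):
        n = k = 0
        for cid, label in comment_labels.items():
            count = per_user[comment_authors[cid]]
            if a < count <= b:
                n += 1
                if label == "recommended":
                    k += 1
        if n == 0:
            continue
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        classes.append(ProlificacyClass(
            a=a, b=b, n=n, k=k, p_hat=k / n, ci_low=float(lo), ci_high=float(hi),
        ))
    return classes


def label_all_users(
    corpus: Corpus,
    comment_schedule_labels: Dict[str, str],
    comment_experience_labels: Optional[Dict[str, str]] = None,
) -> Tuple[Dict[str, UserScheduleLabel], Dict[str, UserExperienceLabel]]:
    """Aggregate comment-level labels for every user with labeled comments."""
    by_user: Dict[str, List[Tuple[str, datetime]]] = {}
    exp_by_user: Dict[str, List[str]] = {}
    comment_experience_labels = comment_experience_labels or {}
    for c in corpus.comments:
        if c.comment_id in comment_schedule_labels:
            by_user.setdefault(c.user_id, []).append(
                (comment_schedule_labels[c.comment_id], c.timestamp)
            )
        if c.comment_id in comment_experience_labels:
            exp_by_user.setdefault(c.user_id, []).append(
                comment_experience_labels[c.comment_id]
            )
    schedule = {
        uid: aggregate_schedule_labels(pairs, user_id=uid)
        for uid, pairs in by_user.items()
    }
    experience = {
        uid: aggregate_experience_labels(labels, user_id=uid)
        for uid, labels in exp_by_user.items()
    }
    return schedule, experience
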