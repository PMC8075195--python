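"""Canonical in-memory data model for forum corpora.

A corpus is three collections — posts, threaded comments, and (partial) user
profiles — stored on disk as three UTF-8 JSON-lines files (``posts.jsonl``,
``comments.jsonl``, ``profiles.jsonl``), one record per line.  Profiles are
optional per user: on the platform studied only about half of the users have a
public profile, so non-public users are represented with ``public=False`` and
an empty group set rather than omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "ForumPost", "ForumComment", "UserProfile", "Corpus", "AnnotationRecord",
    "load_corpus", "write_corpus", "integrity_check",
    "CorpusParseError", "CorpusIntegrityError",
]

SCHEDULE_LABELS = frozenset({"recommended", "alternative", "unrelated"})
EXPERIENCE_LABELS = frozenset(
    {"negative_experience", "positive_experience", "unrelated"}
)


class CorpusParseError(ValueError):
    """A corpus file contained a malformed record (message names the line)."""


class CorpusIntegrityError(ValueError):
    """A corpus violated a referential-integrity invariant."""


def _parse_ts(value: str) -> datetime:
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _format_ts(ts: datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass(frozen=True)
class ForumPost:
    post_id: str
    user_id: str
    timestamp: datetime
    title: str
    body: str

    def to_record(self) -> dict:
        return {
            "post_id": self.post_id,
            "user_id": self.user_id,
            "timestamp": _format_ts(self.timestamp),
            "title": self.title,
            "body": self.body,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ForumPost":
        return cls(
            post_id=str(rec["post_id"]),
            user_id=str(rec["user_id"]),
            timestamp=_parse_ts(rec["timestamp"]),
            title=rec["title"],
            body=rec["body"],
        )


@dataclass(frozen=True)
class ForumComment:
    comment_id: str
    post_id: str
    user_id: str
    timestamp: datetime
    text: str

    def to_record(self) -> dict:
        return {
            "comment_id": self.comment_id,
            "post_id": self.post_id,
            "user_id": self.user_id,
            "timestamp": _format_ts(self.timestamp),
            "text": self.text,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ForumComment":
        return cls(
            comment_id=str(rec["comment_id"]),
            post_id=str(rec["post_id"]),
            user_id=str(rec["user_id"]),
            timestamp=_parse_ts(rec["timestamp"]),
            text=rec["text"],
        )


@dataclass(frozen=True)
class UserProfile:
    user_id: str
    self_reported_location: Optional[str] = None
    groups: frozenset = frozenset()
    public: bool = True

    def to_record(self) -> dict:
        return {
            "user_id": self.user_id,
            "self_reported_location": self.self_reported_location,
            "groups": sorted(self.groups),
            "public": self.public,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "UserProfile":
        return cls(
            user_id=str(rec["user_id"]),
            self_reported_location=rec.get("self_reported_location"),
            groups=frozenset(rec.get("groups", ())),
            public=bool(rec.get("public", True)),
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """One manual label by one annotator for one comment.

    The label must come from exactly one of the two annotation tasks:
    schedule adherence (recommended / alternative / unrelated) or AEFI
    experience (negative_experience / positive_experience / unrelated).
    """

    comment_id: str
    annotator_id: str
    label: str

    def __post_init__(self):
        if self.label not in SCHEDULE_LABELS | EXPERIENCE_LABELS:
            raise ValueError(f"unknown annotation label: {self.label!r}")


@dataclass
class Corpus:
    posts: list = field(default_factory=list)
    comments: list = field(default_factory=list)
    profiles: list = field(default_factory=list)

    def post_by_id(self) -> dict:
        return {p.post_id: p for p in self.posts}

    def profile_by_user(self) -> dict:
        return {p.user_id: p for p in self.profiles}

    def comments_by_user(self) -> dict:
        out: dict = {}
        for c in self.comments:
            out.setdefault(c.user_id, []).append(c)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return (
            self.posts == other.posts
            and self.comments == other.comments
            and self.profiles == other.profiles
        )


def integrity_check(corpus: Corpus) -> list:
    """Return a list of human-readable invariant violations (empty = valid).

    Total on arbitrary well-typed input: violations are reported as data,
    never raised.
    """
    violations = []
    post_ids = set()
    for p in corpus.posts:
        if p.post_id in post_ids:
            violations.append(f"duplicate post_id: {p.post_id}")
        post_ids.add(p.post_id)
    comment_ids = set()
    for c in corpus.comments:
        if c.comment_id in comment_ids:
            violations.append(f"duplicate comment_id: {c.comment_id}")
        comment_ids.add(c.comment_id)
        if c.post_id not in post_ids:
            violations.append(
                f"comment {c.comment_id} references nonexistent post {c.post_id}"
            )
    seen_users = set()
    for prof in corpus.profiles:
        if prof.user_id in seen_users:
            violations.append(f"duplicate profile for user_id: {prof.user_id}")
        seen_users.add(prof.user_id)
        if not prof.public and prof.groups:
            violations.append(
                f"non-public profile {prof.user_id} has non-empty groups"
            )
    return violations


def _read_jsonl(path: Path, factory, what: str) -> list:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                records.append(factory(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise CorpusParseError(
                    f"{path.name}:{lineno}: malformed {what} record: {exc}"
                ) from exc
    return records


def _write_jsonl(path: Path, items: Iterable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in items:
            fh.write(json.dumps(item.to_record(), ensure_ascii=False))
            fh.write("\n")


def load_corpus(path) -> Corpus:
    """Load a corpus from a directory of posts/comments/profiles JSONL files.

    Raises FileNotFoundError for a missing file, CorpusParseError naming the
    offending line for a malformed record, and CorpusIntegrityError naming
    the violations when referential integrity fails.
    """
    root = Path(path)
    for name in ("posts.jsonl", "comments.jsonl", "profiles.jsonl"):
        if not (root / name).exists():
            raise FileNotFoundError(f"missing corpus file: {root / name}")
    corpus = Corpus(
        posts=_read_jsonl(root / "posts.jsonl", ForumPost.from_record, "post"),
        comments=_read_jsonl(
            root / "comments.jsonl", ForumComment.from_record, "comment"
        ),
        profiles=_read_jsonl(
            root / "profiles.jsonl", UserProfile.from_record, "profile"
        ),
    )
    violations = integrity_check(corpus)
    if violations:
        raise CorpusIntegrityError("; ".join(violations))
    return corpus


def write_corpus(corpus: Corpus, path) -> None:
    """Write a valid corpus as three JSONL files; round-trips via load_corpus."""
    violations = integrity_check(corpus)
    if violations:
        raise CorpusIntegrityError("; ".join(violations))
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    _write_jsonl(root / "posts.jsonl", corpus.posts)
    _write_jsonl(root / "comments.jsonl", corpus.comments)
    _write_jsonl(root / "profiles.jsonl", corpus.profiles)
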