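from datetime import datetime, timezone

import pytest

from vaxforum.corpus import Corpus, ForumComment, ForumPost, UserProfile
from vaxforum.schedule import default_lexicon
from vaxforum.aefi import default_vocabulary
from vaxforum.synth import SyntheticConfig, generate_corpus


def ts(year=2015, month=6, day=1, hour=12):
    return datetime(year, month, day, hour, tzinfo=timezone.utc)


def make_comment(text, comment_id="c1", post_id="p1", user_id="u1", when=None):
    return ForumComment(comment_id, post_id, user_id, when or ts(), text)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def vocabulary():
    return default_vocabulary()


@pytest.fixture
def tiny_corpus():
    posts = [
        ForumPost("p1", "alice", ts(2015, 1, 1), "Vaccines?", "Thoughts?"),
        ForumPost("p2", "bob", ts(2015, 2, 1), "Schedule question", "Help"),
    ]
    comments = [
        make_comment("I follow the regular vaccination schedule.",
                     "c1", "p1", "bob", ts(2015, 1, 2)),
        make_comment("We do a delayed vaccination schedule.",
                     "c2", "p1", "carol", ts(2015, 1, 3)),
        make_comment("Thanks for sharing!", "c3", "p2", "alice", ts(2015, 2, 2)),
    ]
    profiles = [
        UserProfile("alice", "Austin, TX", frozenset({"Working Moms"}), True),
        UserProfile("bob", None, frozenset({"Texas Moms"}), True),
        UserProfile("carol", None, frozenset(), False),
    ]
    return Corpus(posts=posts, comments=comments, profiles=profiles)


@pytest.fixture(scope="session")
def clean_synthetic():
    """2000-user clean-template corpus with exact ground truth (seeded)."""
    config = SyntheticConfig(n_users=2000, seed=42, hard_fraction=0.0)
    return generate_corpus(config)
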