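import pytest

from vaxforum.corpus import Corpus, ForumPost
from vaxforum.users import (
    aggregate_experience_labels,
    aggregate_schedule_labels,
    compute_activity,
    label_all_users,
    prolificacy_curve,
)

from conftest import make_comment, ts


class TestScheduleAggregation:
    def test_unanimous_labels_propagate(self):
        result = aggregate_schedule_labels(
            [("recommended", ts(2015, 1, 1)), ("recommended", ts(2015, 2, 1))]
        )
        assert result.value == "RSU"
        assert not result.conflict_resolved
        assert result.n_schedule_comments == 2

    def test_majority_wins_on_conflict(self):
        result = aggregate_schedule_labels([
            ("recommended", ts(2015, 1, 1)),
            ("alternative", ts(2015, 2, 1)),
            ("alternative", ts(2015, 3, 1)),
        ])
        assert result.value == "ASU" and result.conflict_resolved

    def test_exact_tie_resolves_to_latest(self):
        result = aggregate_schedule_labels([
            ("recommended", ts(2015, 1, 1)),
            ("alternative", ts(2015, 6, 1)),
        ])
        assert result.value == "ASU"
        flipped = aggregate_schedule_labels([
            ("recommended", ts(2015, 6, 1)),
            ("alternative", ts(2015, 1, 1)),
        ])
        assert flipped.value == "RSU"

    def test_order_invariant_except_ties(self):
        pairs = [
            ("recommended", ts(2015, 1, 1)),
            ("alternative", ts(2015, 2, 1)),
            ("alternative", ts(2015, 3, 1)),
        ]
        assert (
            aggregate_schedule_labels(pairs).value
            == aggregate_schedule_labels(pairs[::-1]).value
        )

    def test_custom_rule_is_injectable(self):
        any_alternative = lambda pairs: (
            "alternative"
            if any(l == "alternative" for l, _ in pairs) else "recommended"
        )
        result = aggregate_schedule_labels(
            [("alternative", ts(2015, 1, 1))] + [("recommended", ts(2015, 2, 1))] * 5,
            rule=any_alternative,
        )
        assert result.value == "ASU"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_schedule_labels([])


class TestExperienceAggregation:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["positive_experience", "positive_experience", "negative_experience"],
             "reporting_negative"),
            (["positive_experience"], "reporting_positive"),
            (["negative_experience"], "reporting_negative"),
        ],
    )
    def test_any_negative_dominates(self, labels, expected):
        assert aggregate_experience_labels(labels).value == expected

    def test_order_invariant(self):
        labels = ["positive_experience"] * 3 + ["negative_experience"]
        assert (
            aggregate_experience_labels(labels).value
            == aggregate_experience_labels(labels[::-1]).value
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_experience_labels([])


class TestActivity:
    def make_corpus(self):
        posts = [
            ForumPost("p1", "alice", ts(2015, 1, 1), "t", "b"),
            ForumPost("p2", "alice", ts(2015, 2, 1), "t", "b"),
        ]
        comments = [
            make_comment("a", "c1", "p1", "alice", ts(2015, 1, 2)),
            make_comment("b", "c2", "p1", "alice", ts(2016, 3, 27)),
            make_comment("c", "c3", "p2", "alice", ts(2015, 6, 1)),
            make_comment("d", "c4", "p1", "bob", ts(2015, 1, 5)),
        ]
        return Corpus(posts=posts, comments=comments)

    def test_counts_and_tau(self):
        stats = compute_activity(self.make_corpus(), "alice")
        assert stats.n_posts == 2 and stats.n_comments == 3
        assert stats.tau == 450  # 2015-01-02 .. 2016-03-27
        assert not stats.single_day
        # replies received under alice's posts, incl. her own comments
        assert stats.comments_received_per_post == [1, 3]

    def test_single_comment_user_flagged(self):
        stats = compute_activity(self.make_corpus(), "bob")
        assert stats.tau == 0 and stats.single_day

    def test_unknown_user_raises(self):
        with pytest.raises(KeyError):
            compute_activity(self.make_corpus(), "nobody")


class TestProlificacyCurve:
    def test_partition_and_pure_class(self):
        # u1 wrote 1 schedule comment (all recommended), u2 wrote 3
        labels = {"c1": "recommended", "c2": "alternative",
                  "c3": "alternative", "c4": "recommended"}
        authors = {"c1": "u1", "c2": "u2", "c3": "u2", "c4": "u2"}
        classes = prolificacy_curve(labels, authors, bounds=(0, 1, 2, 4))
        assert sum(c.n for c in classes) == 4
        first = classes[0]
        assert (first.a, first.b, first.n, first.p_hat) == (0, 1, 1, 1.0)
        assert first.ci_low <= first.p_hat <= first.ci_high

    def test_empty_classes_omitted(self):
        labels = {"c1": "recommended"}
        authors = {"c1": "u1"}
        classes = prolificacy_curve(labels, authors, bounds=(0, 1, 2, 4, 8))
        assert [(c.a, c.b) for c in classes] == [(0, 1)]

    def test_overlapping_bounds_rejected(self):
        with pytest.raises(ValueError):
            prolificacy_curve({}, {}, bounds=(0, 2, 1))

    def test_weighted_mean_of_classes_equals_overall_fraction(self, clean_synthetic):
        from vaxforum.schedule import run_schedule_pipeline

        corpus, _ = clean_synthetic
        labels = run_schedule_pipeline(corpus)
        authors = {c.comment_id: c.user_id for c in corpus.comments}
        classes = prolificacy_curve(labels, authors)
        total = sum(c.n for c in classes)
        assert total == len(labels)
        weighted = sum(c.n * c.p_hat for c in classes) / total
        overall = sum(1 for v in labels.values() if v == "recommended") / total
        assert weighted == pytest.approx(overall)

    def test_probability_decreases_when_asu_are_more_prolific(self):
        # the generator gives ASUs a higher schedule-comment intensity, so
        # the recommended fraction must fall across prolificacy classes
        from vaxforum.schedule import run_schedule_pipeline
        from vaxforum.synth import SyntheticConfig, generate_corpus

        corpus, _ = generate_corpus(
            SyntheticConfig(n_users=1500, seed=23, asu_prolificacy_boost=3.0)
        )
        labels = run_schedule_pipeline(corpus)
        authors = {c.comment_id: c.user_id for c in corpus.comments}
        classes = prolificacy_curve(labels, authors, bounds=(0, 1, 2, float("inf")))
        assert len(classes) >= 2
        p_hats = [c.p_hat for c in classes]
        assert all(a >= b for a, b in zip(p_hats, p_hats[1:]))
        assert p_hats[0] > p_hats[-1]


def test_label_all_users_end_to_end(clean_synthetic):
    from vaxforum.aefi import run_aefi_pipeline
    from vaxforum.schedule import run_schedule_pipeline

    corpus, truth = clean_synthetic
    schedule = run_schedule_pipeline(corpus)
    aefi = {cid: res[0] for cid, res in run_aefi_pipeline(corpus).items()}
    user_sched, user_exp = label_all_users(corpus, schedule, aefi)
    # every labeled user matches their generating leaning on a clean corpus
    for uid, label in user_sched.items():
        assert label.value == truth.user_schedule_label[uid]
    assert user_sched and user_exp
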