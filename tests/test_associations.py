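import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from vaxforum.associations import (
    ContingencyTable,
    UndefinedOddsRatioError,
    cohen_kappa,
    comment_domains,
    default_gazetteer,
    evaluation_metrics,
    extract_domains,
    fisher_exact,
    geolocate_user,
    odds_ratio_ci,
    population_correlation,
    screen_groups,
    state_populations,
)
from vaxforum.corpus import UserProfile

from conftest import make_comment


def enumeration_fisher(a, b, c, d):
    """Independent oracle: exact hypergeometric enumeration at fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in support
    }
    cutoff = pmf[a] * (1 + Fraction(1, 10 ** 7))
    return float(sum(p for p in pmf.values() if p <= cutoff))


class TestOddsRatio:
    def test_reproduces_aefi_association(self):
        # ASU vs RSU odds of reporting a negative AEFI experience
        table = ContingencyTable(a=2086, b=356, c=1277, d=431,
                                 group_labels=("ASU", "RSU"),
                                 feature_label="negative experience")
        result = odds_ratio_ci(table)
        assert result.odds_ratio == pytest.approx(1.98, abs=0.005)
        assert result.ci_low == pytest.approx(1.69, abs=0.005)
        assert result.ci_high == pytest.approx(2.31, abs=0.005)

    def test_balanced_table_is_one(self):
        assert odds_ratio_ci(ContingencyTable(10, 10, 10, 10)).odds_ratio == 1.0

    def test_hand_arithmetic(self):
        assert odds_ratio_ci(ContingencyTable(2, 8, 8, 2)).odds_ratio == \
            pytest.approx(1 / 16)

    def test_zero_cell_continuity_correction_flagged(self):
        result = odds_ratio_ci(ContingencyTable(0, 10, 5, 5))
        assert result.continuity_corrected
        assert result.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_degenerate_table_raises(self):
        with pytest.raises(UndefinedOddsRatioError):
            odds_ratio_ci(ContingencyTable(0, 0, 5, 5))

    @settings(derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_row_swap_inverts_odds_ratio(self, cells):
        table = ContingencyTable(*cells)
        fwd = odds_ratio_ci(table)
        rev = odds_ratio_ci(table.swapped_rows())
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestFisher:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_matches_enumeration_on_fixture(self):
        assert fisher_exact(ContingencyTable(1, 9, 11, 3)) == \
            pytest.approx(enumeration_fisher(1, 9, 11, 3), rel=1e-9)

    @settings(derandomize=True, max_examples=80)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_matches_enumeration_for_small_tables(self, cells):
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        assert fisher_exact(ContingencyTable(a, b, c, d)) == \
            pytest.approx(enumeration_fisher(a, b, c, d), rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_p_value_is_a_probability(self, cells):
        p = fisher_exact(ContingencyTable(*cells))
        assert 0 < p <= 1


class TestGroupScreen:
    def test_group_joined_only_by_asus_is_retained(self):
        labels = {f"a{i}": "ASU" for i in range(30)}
        labels.update({f"r{i}": "RSU" for i in range(30)})
        profiles = [
            UserProfile(uid, None,
                        frozenset({"Crunchy Circle"} if uid.startswith("a") and i < 20 else set()),
                        True)
            for i, uid in enumerate(labels)
        ]
        retained = screen_groups(labels, profiles)
        assert [g for g, _ in retained] == ["Crunchy Circle"]
        assert retained[0][1].odds_ratio > 1

    def test_zero_member_groups_skipped(self):
        labels = {"u1": "ASU", "u2": "RSU"}
        profiles = [UserProfile("u1", None, frozenset(), True),
                    UserProfile("u2", None, frozenset(), True)]
        assert screen_groups(labels, profiles) == []

    def test_null_group_retained_at_about_alpha(self):
        # a modest version of the type-I simulation (the full 2000-replicate
        # run lives in the acceptance suite)
        rng = np.random.default_rng(4)
        n_users, n_groups = 400, 400
        labels = {
            f"u{i}": ("ASU" if rng.random() < 0.595 else "RSU")
            for i in range(n_users)
        }
        member = rng.random((n_users, n_groups)) < 0.3
        profiles = [
            UserProfile(f"u{i}", None,
                        frozenset(f"g{j}" for j in np.flatnonzero(member[i])), True)
            for i in range(n_users)
        ]
        rate = len(screen_groups(labels, profiles)) / n_groups
        assert 0.01 <= rate <= 0.1


class TestDomains:
    def test_host_reduction(self):
        assert comment_domains("see https://www.cdc.gov/vaccines") == {"cdc.gov"}
        assert comment_domains(
            "x https://pediatrics.aappublications.org/content/1"
        ) == {"pediatrics.aappublications.org"}

    def test_registrable_mode_collapses_subdomains(self):
        assert comment_domains(
            "x https://pediatrics.aappublications.org/c", registrable=True
        ) == {"aappublications.org"}
        assert comment_domains(
            "x https://www.ncbi.nlm.nih.gov/pubmed", registrable=True
        ) == {"ncbi.nlm.nih.gov"}

    def test_comment_level_presence_counts_once(self):
        comments = [make_comment(
            "https://cdc.gov/a and https://www.cdc.gov/b", "c1", "p1", "u1"
        )]
        (count,) = extract_domains(comments, {"u1": "RSU"})
        assert (count.domain, count.n_comments_rsu, count.n_comments_asu) == \
            ("cdc.gov", 1, 0)

    def test_no_urls_yields_empty(self):
        assert extract_domains([make_comment("no links here")], {"u1": "RSU"}) == []

    def test_split_by_author_leaning_and_sorted(self):
        comments = [
            make_comment("https://nvic.org/x", "c1", "p1", "asu1"),
            make_comment("https://nvic.org/y", "c2", "p1", "asu2"),
            make_comment("https://cdc.gov/z", "c3", "p1", "rsu1"),
            make_comment("https://cdc.gov/w", "c4", "p1", "unlabeled"),
        ]
        labels = {"asu1": "ASU", "asu2": "ASU", "rsu1": "RSU"}
        counts = extract_domains(comments, labels)
        assert [(d.domain, d.n_comments_rsu, d.n_comments_asu) for d in counts] == \
            [("nvic.org", 0, 2), ("cdc.gov", 1, 0)]


class TestGeolocation:
    def test_self_report_abbreviation(self):
        profile = UserProfile("u1", "Austin, TX", frozenset(), True)
        result = geolocate_user(profile)
        assert (result.state, result.source) == ("Texas", "self_report")

    def test_local_group_fallback(self):
        profile = UserProfile("u1", None, frozenset({"Texas Moms"}), True)
        result = geolocate_user(profile)
        assert (result.state, result.source) == ("Texas", "local_group")

    def test_self_report_wins_over_group(self):
        profile = UserProfile(
            "u1", "Portland, Oregon", frozenset({"Texas Moms"}), True
        )
        result = geolocate_user(profile)
        assert (result.state, result.source) == ("Oregon", "both")

    def test_no_signal_yields_none(self):
        assert geolocate_user(UserProfile("u1", None, frozenset(), True)).state is None

    def test_private_profile_never_geolocated(self):
        profile = UserProfile("u1", None, frozenset(), False)
        assert geolocate_user(profile).state is None

    def test_gazetteer_covers_51_states(self):
        assert len(default_gazetteer().states) == 51


class TestPopulationCorrelation:
    def test_proportional_counts_give_r_one(self):
        pops = state_populations()
        counts = {s: max(1, p // 10000) for s, p in pops.items()}
        r, p, excluded = population_correlation(counts)
        assert r == pytest.approx(1.0, abs=1e-3)
        assert excluded == []

    def test_permuted_counts_decorrelate(self):
        pops = state_populations()
        states = sorted(pops)
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(30):
            vals = [max(1, pops[s] // 10000) for s in states]
            rng.shuffle(vals)
            r, _, _ = population_correlation(dict(zip(states, vals)))
            rs.append(abs(r))
        assert np.mean(rs) < 0.3

    def test_zero_count_states_excluded_and_reported(self):
        counts = {"Texas": 10, "Ohio": 5, "Maine": 2}
        r, p, excluded = population_correlation(counts)
        assert len(excluded) == 48 and "Texas" not in excluded

    def test_too_few_states_raises(self):
        with pytest.raises(ValueError):
            population_correlation({"Texas": 10, "Ohio": 5})


class TestEvaluation:
    def test_perfect_predictions(self):
        ann = {"c1": "alternative", "c2": "recommended"}
        m = evaluation_metrics(ann, ann, positive_label="alternative")
        assert (m.filter_precision, m.sensitivity, m.specificity) == (1, 1, 1)

    def test_filter_precision_hand_count(self):
        predictions = {"c1": "alternative", "c2": "recommended", "c3": "alternative"}
        annotations = {"c1": "alternative", "c2": "unrelated", "c3": "recommended"}
        m = evaluation_metrics(predictions, annotations, "alternative")
        assert m.filter_precision == pytest.approx(2 / 3)

    def test_degenerate_predictor(self):
        predictions = {f"c{i}": "recommended" for i in range(4)}
        annotations = {"c0": "alternative", "c1": "alternative",
                       "c2": "recommended", "c3": "recommended"}
        m = evaluation_metrics(predictions, annotations, "alternative")
        assert (m.sensitivity, m.specificity) == (0.0, 1.0)

    def test_counts_sum_to_evaluated_records(self):
        predictions = {"c1": "alternative", "c2": "recommended",
                       "c3": "alternative", "c4": "recommended"}
        annotations = {"c1": "recommended", "c2": "recommended",
                       "c3": "alternative", "c4": "unrelated"}
        m = evaluation_metrics(predictions, annotations, "alternative")
        assert m.tp + m.fp + m.tn + m.fn == m.n_relevant_retrieved == 3

    def test_empty_annotations_raise(self):
        with pytest.raises(ValueError):
            evaluation_metrics({"c1": "alternative"}, {}, "alternative")


class TestKappa:
    def test_identical_vectors_give_one(self):
        labels = ["recommended", "alternative", "unrelated"] * 4
        assert cohen_kappa(labels, labels).kappa == pytest.approx(1.0)

    def test_constant_annotator_gives_zero(self):
        a = ["recommended"] * 8
        b = ["recommended"] * 4 + ["alternative"] * 4
        assert cohen_kappa(a, b).kappa == pytest.approx(0.0)

    def test_three_label_fixture_by_direct_formula(self):
        a = ["r", "r", "a", "a", "u", "u"]
        b = ["r", "r", "a", "u", "u", "a"]
        # p_o = 4/6, uniform marginals give p_e = 1/3, kappa = 1/2
        result = cohen_kappa(a, b)
        assert result.observed_agreement == pytest.approx(2 / 3)
        assert result.expected_agreement == pytest.approx(1 / 3)
        assert result.kappa == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.sampled_from("rau"), st.sampled_from("rau")),
                    min_size=2, max_size=40))
    def test_matches_sklearn(self, pairs):
        a = [x for x, _ in pairs]
        b = [y for _, y in pairs]
        try:
            ours = cohen_kappa(a, b).kappa
        except ZeroDivisionError:
            return
        assert ours == pytest.approx(float(cohen_kappa_score(a, b)), abs=1e-12)

    def test_degenerate_chance_agreement_raises(self):
        with pytest.raises(ZeroDivisionError):
            cohen_kappa(["r", "r"], ["r", "r"])
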