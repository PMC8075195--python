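"""2x2 association machinery and feature screens.

Everything odds-ratio shaped goes through :class:`ContingencyTable` and
:func:`odds_ratio_ci` (Woolf log-normal interval, Fisher exact screening),
which back the interest-group screen, the AEFI-experience association, the
reaction and subject associations, the URL-domain ranking, the state-level
geolocation with census-population correlation, and the pipeline-evaluation
metrics (filter precision, classifier sensitivity/specificity, Cohen's
kappa for inter-annotator agreement).
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from vaxforum.corpus import ForumComment, UserProfile

__all__ = [
    "ContingencyTable", "ORResult", "EvalMetrics", "KappaResult",
    "StateAssignment", "DomainCount",
    "odds_ratio_ci", "fisher_exact", "screen_groups", "extract_domains",
    "geolocate_user", "population_correlation", "evaluation_metrics",
    "cohen_kappa", "load_state_table", "StateGazetteer", "default_gazetteer",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows are groups, columns feature present/absent."""

    a: int  # group1, feature+
    b: int  # group1, feature-
    c: int  # group2, feature+
    d: int  # group2, feature-
    group_labels: Tuple[str, str] = ("group1", "group2")
    feature_label: str = "feature"

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(
            self.c, self.d, self.a, self.b,
            (self.group_labels[1], self.group_labels[0]), self.feature_label,
        )


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    p_fisher: Optional[float] = None
    continuity_corrected: bool = False


class UndefinedOddsRatioError(ValueError):
    pass


def odds_ratio_ci(table: ContingencyTable, alpha: float = 0.05) -> ORResult:
    """Odds ratio (a*d)/(b*c) with the Woolf log-normal confidence interval.

    CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  A single zero cell
    gets the Haldane-Anscombe 0.5 continuity correction and is flagged; two
    zero cells in one row or column leave the OR undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0) or \
       (a == 0 and c == 0) or (b == 0 and d == 0):
        raise UndefinedOddsRatioError(
            f"odds ratio undefined for table ({a}, {b}, {c}, {d})"
        )
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        odds_ratio=oratio,
        ci_low=oratio * math.exp(-z * se),
        ci_high=oratio * math.exp(z * se),
        alpha=alpha,
        continuity_corrected=corrected,
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (at fixed margins) no more probable than the observed one."""
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(p)


def screen_groups(
    user_labels: Mapping[str, str],
    profiles: Iterable[UserProfile],
    alpha: float = 0.05,
    with_fisher: bool = False,
    min_members: int = 1,
) -> List[Tuple[str, ORResult]]:
    """Screen interest groups for association with schedule adherence.

    One 2x2 table per group (member vs non-member x ASU vs RSU, OR oriented
    toward ASU membership); groups whose Woolf CI excludes 1 are retained,
    sorted by decreasing OR.  No multiple-testing correction is applied: each
    group is screened at its own per-group confidence level.
    """
    labeled_profiles = [
        p for p in profiles if p.public and p.user_id in user_labels
    ]
    groups: Dict[str, set] = {}
    for p in labeled_profiles:
        for g in p.groups:
            groups.setdefault(g, set()).add(p.user_id)
    n_asu = sum(
        1 for p in labeled_profiles if user_labels[p.user_id] == "ASU"
    )
    n_rsu = len(labeled_profiles) - n_asu
    retained = []
    for group, members in sorted(groups.items()):
        if len(members) < min_members:
            continue
        a = sum(1 for u in members if user_labels[u] == "ASU")
        c = len(members) - a
        table = ContingencyTable(
            a=a, b=n_asu - a, c=c, d=n_rsu - c,
            group_labels=("ASU", "RSU"), feature_label=group,
        )
        try:
            result = odds_ratio_ci(table, alpha=alpha)
        except UndefinedOddsRatioError:
            continue
        if with_fisher:
            result = ORResult(
                result.odds_ratio, result.ci_low, result.ci_high,
                result.alpha, fisher_exact(table), result.continuity_corrected,
            )
        if result.ci_low > 1 or result.ci_high < 1:
            retained.append((group, result))
    retained.sort(key=lambda item: -item[1].odds_ratio)
    return retained


# ---------------------------------------------------------------------------
# URL domains

_URL_RE = re.compile(r"https?://([^\s/\"'<>]+)", re.IGNORECASE)

# minimal multi-part public suffixes for registrable-domain mode
_TWO_PART_SUFFIXES = {
    "co.uk", "org.uk", "ac.uk", "gov.uk", "com.au", "net.au", "org.au",
    "co.nz", "co.jp", "com.br", "com.mx", "nlm.nih.gov",
}


@dataclass(frozen=True)
class DomainCount:
    domain: str
    n_comments_rsu: int
    n_comments_asu: int

    @property
    def total(self) -> int:
        return self.n_comments_rsu + self.n_comments_asu


def _reduce_host(host: str, registrable: bool) -> str:
    host = host.lower().split(":")[0].rstrip(".")
    if host.startswith("www."):
        host = host[4:]
    if not registrable:
        return host
    parts = host.split(".")
    for k in (3, 2):
        if len(parts) > k and ".".join(parts[-k:]) in _TWO_PART_SUFFIXES:
            return ".".join(parts[-(k + 1):])
    if len(parts) > 2 and ".".join(parts[-2:]) in _TWO_PART_SUFFIXES:
        return host
    return ".".join(parts[-2:]) if len(parts) >= 2 else host


def comment_domains(text: str, registrable: bool = False) -> FrozenSet[str]:
    """Distinct reduced domains cited in one comment."""
    return frozenset(
        _reduce_host(m.group(1), registrable) for m in _URL_RE.finditer(text)
    )


def extract_domains(
    comments: Iterable[ForumComment],
    user_labels: Mapping[str, str],
    registrable: bool = False,
) -> List[DomainCount]:
    """Count, per domain, the comments of RSUs and ASUs citing it.

    A comment citing the same domain twice counts once; the default
    reduction keeps the full host minus a leading "www." (so
    pediatrics.aappublications.org survives); ``registrable=True`` collapses
    to the public-suffix registrable domain instead.
    """
    counts: Dict[str, List[int]] = {}
    for comment in comments:
        label = user_labels.get(comment.user_id)
        if label not in ("RSU", "ASU"):
            continue
        for domain in comment_domains(comment.text, registrable):
            slot = counts.setdefault(domain, [0, 0])
            slot[0 if label == "RSU" else 1] += 1
    out = [
        DomainCount(domain, rsu, asu) for domain, (rsu, asu) in counts.items()
    ]
    out.sort(key=lambda d: (-d.total, d.domain))
    return out


# ---------------------------------------------------------------------------
# Geolocation

@dataclass(frozen=True)
class StateAssignment:
    user_id: str
    state: Optional[str]
    source: Optional[str]  # self_report | local_group | both


class StateGazetteer:
    """Maps state names/abbreviations and local-group names to states."""

    def __init__(self, names_to_state: Mapping[str, str]):
        self._index = {k.lower(): v for k, v in names_to_state.items()}
        self._states = sorted(set(names_to_state.values()))
        self._name_patterns = [
            (re.compile(rf"\b{re.escape(name)}\b", re.IGNORECASE), state)
            for name, state in names_to_state.items()
            if len(name) > 2  # full names only for substring search
        ]

    @property
    def states(self) -> List[str]:
        return self._states

    def resolve_location(self, text: Optional[str]) -> Optional[str]:
        if not text:
            return None
        # trailing ", XX" abbreviation wins, then any full state name
        for chunk in reversed([c.strip() for c in text.split(",")]):
            token = chunk.split()[0].rstrip(".") if chunk else ""
            hit = self._index.get(token.lower())
            if hit:
                return hit
        for pattern, state in self._name_patterns:
            if pattern.search(text):
                return state
        return None

    def resolve_group(self, group_name: str) -> Optional[str]:
        for pattern, state in self._name_patterns:
            if pattern.search(group_name):
                return state
        return None


def load_state_table() -> List[Dict[str, str]]:
    path = Path(__file__).parent / "data" / "states.csv"
    with open(path, encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def default_gazetteer() -> StateGazetteer:
    names: Dict[str, str] = {}
    for row in load_state_table():
        names[row["state"]] = row["state"]
        names[row["abbrev"]] = row["state"]
    return StateGazetteer(names)


def state_populations() -> Dict[str, int]:
    return {
        row["state"]: int(row["population_2010"]) for row in load_state_table()
    }


def geolocate_user(
    profile: UserProfile, gazetteer: Optional[StateGazetteer] = None
) -> StateAssignment:
    """Assign one of the 51 US states (50 + DC) to a user.

    The self-reported profile location is resolved first; membership in a
    state-named local group is the fallback.  When both signals exist the
    self-report wins and the source is recorded as "both".
    """
    gazetteer = gazetteer or default_gazetteer()
    from_location = (
        gazetteer.resolve_location(profile.self_reported_location)
        if profile.public else None
    )
    from_group = None
    if profile.public:
        for group in sorted(profile.groups):
            from_group = gazetteer.resolve_group(group)
            if from_group:
                break
    if from_location and from_group:
        return StateAssignment(profile.user_id, from_location, "both")
    if from_location:
        return StateAssignment(profile.user_id, from_location, "self_report")
    if from_group:
        return StateAssignment(profile.user_id, from_group, "local_group")
    return StateAssignment(profile.user_id, None, None)


def population_correlation(
    state_user_counts: Mapping[str, int],
    populations: Optional[Mapping[str, int]] = None,
) -> Tuple[float, float, List[str]]:
    """Pearson r between log user counts and log state populations.

    States with zero mapped users are excluded (and returned) since the log
    transform is undefined there.  Returns (r, p, excluded_states).
    """
    populations = populations or state_populations()
    included, excluded = [], []
    for state, pop in populations.items():
        n = state_user_counts.get(state, 0)
        if n > 0:
            included.append((n, pop))
        else:
            excluded.append(state)
    if len(included) < 3:
        raise ValueError("need at least 3 states with users for a correlation")
    counts = np.log(np.array([n for n, _ in included], dtype=float))
    pops = np.log(np.array([p for _, p in included], dtype=float))
    r, p = stats.pearsonr(counts, pops)
    return float(r), float(p), sorted(excluded)


# ---------------------------------------------------------------------------
# Evaluation harness

@dataclass(frozen=True)
class EvalMetrics:
    filter_precision: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_retrieved: int
    n_relevant_retrieved: int


def evaluation_metrics(
    predictions: Mapping[str, str],
    annotations: Mapping[str, str],
    positive_label: str,
) -> EvalMetrics:
    """Evaluate filter + classifier against manual annotations.

    Filter precision is the fraction of retrieved (predicted) comments whose
    annotation is not "unrelated".  Sensitivity/specificity are computed on
    the retrieved comments that are related, with ``positive_label`` as the
    positive class (alternative for the schedule task, negative_experience
    for the AEFI task).
    """
    if not annotations:
        raise ValueError("empty annotation set")
    retrieved = [cid for cid in predictions if cid in annotations]
    relevant = [cid for cid in retrieved if annotations[cid] != "unrelated"]
    tp = fp = tn = fn = 0
    for cid in relevant:
        pred_pos = predictions[cid] == positive_label
        true_pos = annotations[cid] == positive_label
        if true_pos and pred_pos:
            tp += 1
        elif true_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    precision = len(relevant) / len(retrieved) if retrieved else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return EvalMetrics(
        filter_precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_retrieved=len(retrieved),
        n_relevant_retrieved=len(relevant),
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def cohen_kappa(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> KappaResult:
    """Cohen's kappa between two annotators over the same comment set.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    annotators' marginal label frequencies.
    """
    if len(labels_a) != len(labels_b) or not labels_a:
        raise ValueError("annotators must label the same non-empty set")
    n = len(labels_a)
    p_o = sum(x == y for x, y in zip(labels_a, labels_b)) / n
    cats = set(labels_a) | set(labels_b)
    p_e = sum(
        (labels_a.count(c) / n) * (labels_b.count(c) / n) for c in cats
    )
    if p_e == 1:
        raise ZeroDivisionError("kappa undefined: chance agreement is 1")
    return KappaResult(
        kappa=(p_o - p_e) / (1 - p_e),
        observed_agreement=p_o,
        expected_agreement=p_e,
    )
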