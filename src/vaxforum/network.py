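"""Directed weighted commenter-to-author interaction network.

Nodes are schedule-labeled users; there is an edge i -> j (weight w_ij) when
user i wrote w_ij comments under posts authored by user j.  Each user carries
a leaning: +1 for RSUs, -1 for ASUs.  The echo-chamber analysis looks at the
joint distribution of the weighted average leaning of a user's in-neighbors
(users commenting on their posts) and out-neighbors (authors they comment
on): an echo chamber would concentrate mass at (+1,+1) for RSUs and (-1,-1)
for ASUs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from vaxforum.corpus import Corpus

__all__ = [
    "InteractionGraph", "LeaningSummary", "JointLeaningDistribution",
    "build_graph", "neighbor_leaning", "leaning_summaries",
    "joint_distribution",
]

LEANING = {"RSU": 1.0, "ASU": -1.0}


@dataclass
class InteractionGraph:
    """Wrapper around a networkx DiGraph with node attribute ``leaning``."""

    graph: nx.DiGraph

    def leaning(self, user_id: str) -> float:
        return self.graph.nodes[user_id]["leaning"]

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.graph.edges(data="weight"))


@dataclass(frozen=True)
class LeaningSummary:
    user_id: str
    leaning: float
    in_avg: Optional[float]
    out_avg: Optional[float]


@dataclass(frozen=True)
class JointLeaningDistribution:
    group: str
    bin_edges: np.ndarray  # shared by both axes
    mass: np.ndarray  # normalized, axis 0 = in_avg, axis 1 = out_avg
    n_users: int
    n_excluded: int  # group users lacking a defined in_avg or out_avg


def build_graph(corpus: Corpus, user_labels: Mapping[str, str]) -> InteractionGraph:
    """Build the commenter->author graph over schedule-labeled users.

    Edge i->j iff labeled user i commented at least once under a post by
    labeled user j, i != j (commenting on one's own post is not an
    inter-user interaction); weight = number of such comments.
    """
    g = nx.DiGraph()
    for uid, label in user_labels.items():
        g.add_node(uid, leaning=LEANING[label])
    post_author = {p.post_id: p.user_id for p in corpus.posts}
    for c in corpus.comments:
        if c.user_id not in user_labels:
            continue
        author = post_author.get(c.post_id)
        if author is None or author == c.user_id or author not in user_labels:
            continue
        if g.has_edge(c.user_id, author):
            g[c.user_id][author]["weight"] += 1
        else:
            g.add_edge(c.user_id, author, weight=1)
    return InteractionGraph(g)


def neighbor_leaning(
    graph: InteractionGraph, user_id: str, direction: str
) -> Optional[float]:
    """Weighted mean leaning of in- or out-neighbors; None when isolated
    in that direction.  Invariant to uniform rescaling of all weights."""
    g = graph.graph
    if user_id not in g:
        raise KeyError(f"unknown user: {user_id}")
    if direction == "in":
        edges = [(src, data["weight"]) for src, _, data in g.in_edges(user_id, data=True)]
    elif direction == "out":
        edges = [(dst, data["weight"]) for _, dst, data in g.out_edges(user_id, data=True)]
    else:
        raise ValueError("direction must be 'in' or 'out'")
    if not edges:
        return None
    total = sum(w for _, w in edges)
    return sum(g.nodes[nbr]["leaning"] * w for nbr, w in edges) / total


def leaning_summaries(graph: InteractionGraph) -> Dict[str, LeaningSummary]:
    out = {}
    for uid in graph.graph.nodes:
        out[uid] = LeaningSummary(
            user_id=uid,
            leaning=graph.leaning(uid),
            in_avg=neighbor_leaning(graph, uid, "in"),
            out_avg=neighbor_leaning(graph, uid, "out"),
        )
    return out


def mixture_calibration(
    graph: InteractionGraph,
    commenter_counts: Mapping[str, int],
    asu_fraction: float,
) -> Tuple[float, float, float]:
    """Observed mean in-neighbor leaning vs. the population-mixture expectation.

    Under no homophily the expected neighbor leaning is ``2*(1-asu_fraction)-1``.
    The sampling error of the comparison has two parts: the per-user spread of
    the in-neighbor averages, and the common-mode fluctuation of the realized
    comment-weighted leaning mixture (heavy-tailed commenters shift every
    user's average together, so the naive per-user standard error alone is
    anti-conservative).  Returns (observed mean, expected, combined SE).
    """
    vals = np.array([
        v for v in (
            neighbor_leaning(graph, uid, "in") for uid in graph.graph.nodes
        ) if v is not None
    ])
    if vals.size == 0:
        raise ValueError("no users with defined in-neighbor leaning")
    se_users = float(vals.std() / np.sqrt(vals.size))
    counts = np.array(list(commenter_counts.values()), dtype=float)
    p = asu_fraction
    se_mixture = float(
        np.sqrt((counts ** 2).sum() * 4 * p * (1 - p)) / counts.sum()
    )
    expected = 2 * (1 - asu_fraction) - 1
    return float(vals.mean()), expected, float(np.hypot(se_users, se_mixture))


def joint_distribution(
    graph: InteractionGraph,
    group: str,
    bins: int = 21,
    swap_directions: bool = False,
) -> JointLeaningDistribution:
    """Normalized 2D histogram of (in_avg, out_avg) for one group's users.

    Users lacking either average (isolated in one direction) cannot be
    placed and are excluded but counted.  ``swap_directions`` exchanges the
    axes, for reading the network with in-neighbors as "authors attended
    to" rather than "users commenting on my posts".
    """
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    target = LEANING[group]
    points = []
    excluded = 0
    for summary in leaning_summaries(graph).values():
        if summary.leaning != target:
            continue
        if summary.in_avg is None or summary.out_avg is None:
            excluded += 1
            continue
        if swap_directions:
            points.append((summary.out_avg, summary.in_avg))
        else:
            points.append((summary.in_avg, summary.out_avg))
    if not points:
        raise ValueError(f"no {group} users with both neighbor averages defined")
    arr = np.array(points)
    edges = np.linspace(-1.0, 1.0, bins + 1)
    hist, _, _ = np.histogram2d(arr[:, 0], arr[:, 1], bins=(edges, edges))
    return JointLeaningDistribution(
        group=group,
        bin_edges=edges,
        mass=hist / hist.sum(),
        n_users=len(points),
        n_excluded=excluded,
    )
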