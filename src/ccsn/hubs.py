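"""Hub-gene ranking by Maximal Clique Centrality (MCC).

MCC(v) sums (|C| - 1)! over the maximal cliques C that contain v.  An
isolated node scores 0; a node none of whose neighbors are adjacent to
each other scores its degree, because each of its edges is then itself a
maximal clique (the convention of the cytoHubba reference tool).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx

__all__ = ["maximal_cliques", "mcc_scores", "top_hubs", "HubRanking"]

logger = logging.getLogger(__name__)


@dataclass
class HubRanking:
    """Competition-ranked hub list: tied scores share a rank."""

    entries: list[tuple[int, Hashable, int]]  # (rank, gene, mcc score)

    def genes(self) -> list[Hashable]:
        return [g for _, g, _ in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def maximal_cliques(graph: nx.Graph) -> list[set]:
    """All maximal cliques, including singletons for isolated nodes."""
    return [set(c) for c in nx.find_cliques(graph)]


def mcc_scores(graph: nx.Graph) -> dict[Hashable, int]:
    """Maximal clique centrality of every node.

    Sum of (|C| - 1)! over maximal cliques of size >= 2 containing the
    node; 0 for isolated nodes.  The degree fallback for edge-only
    neighborhoods is automatic: each such edge is a maximal 2-clique
    contributing 1! = 1.
    """
    scores: dict[Hashable, int] = {v: 0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def top_hubs(scores: Mapping[Hashable, int], k: int = 20) -> HubRanking:
    """Top-k genes by MCC with competition ranking (ties share a rank).

    Deterministic: ties are ordered by gene id.  If fewer than k genes
    are scored, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(scores) < k:
        logger.warning("only %d scored genes for top-%d request", len(scores), k)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))[:k]
    entries: list[tuple[int, Hashable, int]] = []
    for pos, (gene, score) in enumerate(ordered, start=1):
        if entries and score == entries[-1][2]:
            rank = entries[-1][0]
        else:
            rank = pos
        entries.append((rank, gene, int(score)))
    return HubRanking(entries)
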