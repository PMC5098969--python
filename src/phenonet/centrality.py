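"""Weighted node centrality: strength and shortest-path betweenness.

Strength is the sum of absolute incident edge weights.  Betweenness follows
the weighted-network convention of the psychometric tooling: the length of
an edge is the reciprocal of its absolute weight, shortest paths minimize
total length, and tied shortest paths share credit fractionally (Brandes).
Betweenness is reported unnormalized (raw path counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import EDGE_EPS, NetworkModel

__all__ = ["strength", "betweenness", "centrality_table", "CentralityTable"]


def strength(W, v: int | None = None):
    """Sum of absolute edge weights incident to each node (or to node v)."""
    W = np.asarray(W, dtype=float)
    s = np.abs(W).sum(axis=1)
    return s if v is None else float(s[v])


def _graph(W: np.ndarray) -> nx.Graph:
    p = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    iu, ju = np.triu_indices(p, 1)
    for i, j in zip(iu, ju):
        w = W[i, j]
        if abs(w) > EDGE_EPS:
            G.add_edge(int(i), int(j), length=1.0 / abs(w))
    return G


def betweenness(W, v: int | None = None):
    """Unnormalized weighted betweenness with edge length 1/|w|.

    Disconnected pairs contribute nothing; leaves and isolated nodes score 0.
    """
    W = np.asarray(W, dtype=float)
    bc = nx.betweenness_centrality(_graph(W), normalized=False,
                                   weight="length")
    b = np.array([bc[i] for i in range(W.shape[0])])
    return b if v is None else float(b[v])


@dataclass
class CentralityTable:
    """Per-node betweenness b(v) and strength s(v)."""

    labels: list[str]
    betweenness: np.ndarray
    strength: np.ndarray
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.labels,
                "betweenness": self.betweenness,
                "strength": self.strength,
            }
        )


def centrality_table(model: NetworkModel, source: str = "") -> CentralityTable:
    """Both centrality metrics for every node of a network model."""
    return CentralityTable(
        labels=list(model.labels),
        betweenness=betweenness(model.W),
        strength=strength(model.W),
        source=source,
    )
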