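"""Extended core network inference and the single-best-edge baseline.

The extended core network (ECN) keeps, for every gene, all significant
partners whose MI is within an accepting rate ``r`` of the gene's row
maximum; the result is an asymmetric boolean adjacency where
``A[g, g']`` means g' is accepted into g's neighborhood.  ``r = 0``
keeps only the argmax set (with ties), ``r = 1`` keeps every significant
partner.  The baseline keeps exactly one best edge per gene and is
symmetrized into an undirected graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np

from .datatypes import TranscriptID
from .mi import MIMatrix

__all__ = ["CoreNetwork", "ecn_infer", "c3net_infer", "symmetrize"]


@dataclass
class CoreNetwork:
    """Boolean adjacency over an ordered transcript list.

    ``A[i, j]`` is True when transcript j belongs to transcript i's
    accepted neighborhood.  ``directed`` is False after symmetrization
    (A is then symmetric by construction).
    """

    ids: list[TranscriptID]
    A: np.ndarray
    accepting_rate: float | None = None
    directed: bool = True

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=bool)
        if self.A.shape != (len(self.ids), len(self.ids)):
            raise ValueError("adjacency shape does not match id list")
        if self.A.diagonal().any():
            raise ValueError("self-loops are not allowed")
        if not self.directed and not np.array_equal(self.A, self.A.T):
            raise ValueError("undirected network must have symmetric adjacency")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, transcript: TranscriptID | str) -> int:
        key = str(transcript)
        for i, t in enumerate(self.ids):
            if str(t) == key:
                return i
        raise KeyError(key)

    def out_neighbors(self, transcript: TranscriptID | str) -> set[TranscriptID]:
        row = self.A[self.index_of(transcript)]
        return {self.ids[j] for j in np.flatnonzero(row)}

    def edges(self) -> Iterator[tuple[TranscriptID, TranscriptID]]:
        """Directed arcs, or each undirected edge once (i < j)."""
        a = self.A if self.directed else np.triu(self.A)
        for i, j in zip(*np.nonzero(a)):
            yield self.ids[i], self.ids[j]

    def n_edges(self) -> int:
        total = int(self.A.sum())
        return total if self.directed else total // 2

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        g: nx.Graph = nx.DiGraph() if self.directed else nx.Graph()
        for t in self.ids:
            g.add_node(str(t), strand=t.strand.value)
        for u, v in self.edges():
            g.add_edge(str(u), str(v))
        return g


def ecn_infer(mi: MIMatrix, r: float) -> CoreNetwork:
    """Accept every significant partner within rate ``r`` of the row max.

    For gene g with row maximum ``m_g``, partner g' is accepted iff
    ``M[g, g'] > 0`` and ``M[g, g'] >= (1 - r) * m_g``.  Rows with no
    significant MI stay isolated.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("accepting rate must be in [0, 1]")
    m = mi.M
    row_max = m.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        A = (m > 0) & (m >= (1.0 - r) * row_max)
    np.fill_diagonal(A, False)
    return CoreNetwork(list(mi.ids), A, accepting_rate=r, directed=True)


def c3net_infer(mi: MIMatrix, keep_ties: bool = False) -> CoreNetwork:
    """One best edge per gene (first index on ties), symmetrized.

    With ``keep_ties`` every tied maximum is kept, which makes the result
    identical to ``symmetrize(ecn_infer(mi, 0))``.
    """
    m = mi.M
    n = mi.n
    A = np.zeros((n, n), dtype=bool)
    for i in range(n):
        best = m[i].max()
        if best <= 0:
            continue
        if keep_ties:
            A[i, m[i] == best] = True
        else:
            A[i, int(np.argmax(m[i]))] = True
    A |= A.T
    np.fill_diagonal(A, False)
    return CoreNetwork(list(mi.ids), A, accepting_rate=None, directed=False)


def symmetrize(net: CoreNetwork, mode: str = "union") -> CoreNetwork:
    """Undirected view of an asymmetric adjacency (union or intersection)."""
    if mode == "union":
        A = net.A | net.A.T
    elif mode == "intersection":
        A = net.A & net.A.T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoreNetwork(
        list(net.ids), A, accepting_rate=net.accepting_rate, directed=False
    )
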