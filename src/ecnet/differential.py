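"""Differential comparison of the sense (S) and sense+anti-sense (SAS)
extended core networks.

A sense gene is *AS-impacted* when it has neighbors in the S network but
its SAS out-neighborhood, while non-empty, contains only anti-sense
transcripts.  Each such gene defines a *change motif*: the gene with its
direct neighborhoods from both networks, optionally enlarged with the
SAS neighborhoods of the motif's anti-sense actors.  AS-impacted genes
that are connected in the S network form *AS-impacted sub-graphs*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_network import CoreNetwork, symmetrize
from .datatypes import TranscriptID

__all__ = [
    "ChangeMotif",
    "ASImpactedSubgraph",
    "find_as_impacted",
    "build_change_motif",
    "as_impacted_subgraphs",
]

#: edge provenance labels
S_ONLY = "s_only"
SAS_ONLY = "sas_only"
BOTH = "both"


@dataclass
class ChangeMotif:
    center: TranscriptID
    s_neighbors: set[TranscriptID]
    sas_neighbors: set[TranscriptID]
    enlarged: set[TranscriptID] = field(default_factory=set)
    edges: list[tuple[TranscriptID, TranscriptID, str]] = field(default_factory=list)

    def nodes(self) -> set[TranscriptID]:
        return {self.center} | self.s_neighbors | self.sas_neighbors | self.enlarged

    def size(self) -> int:
        return len(self.nodes())


@dataclass
class ASImpactedSubgraph:
    members: set[TranscriptID]
    s_edges: list[tuple[TranscriptID, TranscriptID]]


def _check_sense_consistency(net_S: CoreNetwork, net_SAS: CoreNetwork) -> None:
    sense_S = {str(t) for t in net_S.ids if t.is_sense}
    sense_SAS = {str(t) for t in net_SAS.ids if t.is_sense}
    if sense_S != sense_SAS:
        raise ValueError("sense transcript sets differ between S and SAS networks")


def find_as_impacted(
    net_S: CoreNetwork, net_SAS: CoreNetwork
) -> set[TranscriptID]:
    """Sense genes whose SAS out-neighborhood is non-empty and all anti-sense.

    Requires (a) at least one neighbor in the S network and (b) at least
    one neighbor in the SAS network, none of which is sense.
    """
    _check_sense_consistency(net_S, net_SAS)
    sas_index = {str(t): i for i, t in enumerate(net_SAS.ids)}
    antisense = np.array([t.is_antisense for t in net_SAS.ids])

    impacted: set[TranscriptID] = set()
    for i, g in enumerate(net_S.ids):
        if not g.is_sense or not net_S.A[i].any():
            continue
        row = net_SAS.A[sas_index[str(g)]]
        if row.any() and not (row & ~antisense).any():
            impacted.add(g)
    return impacted


def build_change_motif(
    g: TranscriptID,
    net_S: CoreNetwork,
    net_SAS: CoreNetwork,
    enlarge: bool = False,
) -> ChangeMotif:
    """Direct neighborhoods of an AS-impacted gene in both networks.

    Edges are labeled by provenance (S-only / SAS-only / both).  With
    ``enlarge``, the SAS out-neighborhoods of the motif's anti-sense
    actors are added (their edges labeled from the SAS network).
    """
    if g not in find_as_impacted(net_S, net_SAS):
        raise ValueError(f"{g} is not AS-impacted")

    s_nbrs = net_S.out_neighbors(g)
    sas_nbrs = net_SAS.out_neighbors(g)

    sas_names = {str(t) for t in net_SAS.ids}
    edges: list[tuple[TranscriptID, TranscriptID, str]] = []
    for v in sorted(s_nbrs | sas_nbrs):
        in_s = v in s_nbrs
        in_sas = v in sas_nbrs
        label = BOTH if (in_s and in_sas) else (S_ONLY if in_s else SAS_ONLY)
        edges.append((g, v, label))

    enlarged: set[TranscriptID] = set()
    if enlarge:
        motif_nodes = {g} | s_nbrs | sas_nbrs
        for a in sorted(t for t in sas_nbrs if t.is_antisense):
            if str(a) not in sas_names:
                continue
            for v in sorted(net_SAS.out_neighbors(a)):
                if v not in motif_nodes and v != a:
                    enlarged.add(v)
                if v != a:
                    edges.append((a, v, SAS_ONLY))
    return ChangeMotif(g, s_nbrs, sas_nbrs, enlarged, edges)


def as_impacted_subgraphs(
    net_S: CoreNetwork,
    impacted: set[TranscriptID],
    min_size: int = 3,
) -> list[ASImpactedSubgraph]:
    """Connected components of impacted genes in the symmetrized S network.

    Components with fewer than ``min_size`` members are dropped.  Results
    are sorted by decreasing size, then by smallest member id.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sym = symmetrize(net_S, "union")
    g = sym.to_networkx()
    keep = {str(t) for t in impacted}
    sub = g.subgraph(keep & set(g.nodes))

    out = []
    for comp in nx.connected_components(sub):
        if len(comp) < min_size:
            continue
        members = {TranscriptID.parse(name) for name in comp}
        s_edges = [
            (TranscriptID.parse(u), TranscriptID.parse(v))
            for u, v in sub.subgraph(comp).edges()
        ]
        out.append(ASImpactedSubgraph(members, s_edges))
    out.sort(key=lambda s: (-len(s.members), min(str(t) for t in s.members)))
    return out
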