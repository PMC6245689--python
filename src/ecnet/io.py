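"""Readers and writers for the plain-text interchange formats.

Expression matrices are tab-delimited with transcript IDs in the first
column and sample labels in the header.  Networks are exported as SIF
(``source<TAB>interaction<TAB>target``) and GraphML, both loadable in
Cytoscape.  GO DAGs come from OBO files; annotations from a tab-
delimited gene / GO term / GO-slim table.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_network import CoreNetwork
from .datatypes import ExpressionMatrix, TranscriptID
from .enrichment import AnnotationMap, EnrichmentResult
from .steiner import SteinerTree

__all__ = [
    "read_expression",
    "write_expression",
    "write_sif",
    "read_sif",
    "write_graphml",
    "write_adjacency",
    "read_obo",
    "read_annotations",
    "write_enrichment",
    "write_manifest",
    "write_steiner_tree",
]


# -- expression matrices ---------------------------------------------------

def read_expression(path: str | Path, condition: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    transcripts = [TranscriptID.parse(str(i)) for i in df.index]
    return ExpressionMatrix(
        transcripts, [str(c) for c in df.columns], df.to_numpy(dtype=float),
        condition=condition,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values,
        index=[str(t) for t in matrix.transcripts],
        columns=matrix.samples,
    )
    df.to_csv(path, sep="\t", index_label="transcript", float_format="%.10g")


# -- networks --------------------------------------------------------------

def write_sif(
    edges,
    path: str | Path,
    interaction: str = "mi",
) -> None:
    """Write (source, target) or (source, target, interaction) tuples."""
    with open(path, "w") as fh:
        for edge in edges:
            if len(edge) == 3:
                u, v, kind = edge
            else:
                u, v = edge
                kind = interaction
            fh.write(f"{u}\t{kind}\t{v}\n")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            out.append((parts[0], parts[2], parts[1]))
    return out


def write_network_sif(net: CoreNetwork, path: str | Path,
                      interaction: str = "mi") -> None:
    write_sif(((str(u), str(v)) for u, v in net.edges()), path, interaction)


def write_graphml(net: CoreNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def write_adjacency(net: CoreNetwork, path: str | Path) -> None:
    df = pd.DataFrame(
        net.A.astype(int),
        index=[str(t) for t in net.ids],
        columns=[str(t) for t in net.ids],
    )
    df.to_csv(path, sep="\t", index_label="transcript")


def write_steiner_tree(tree: SteinerTree, sif_path: str | Path,
                       attr_path: str | Path | None = None) -> None:
    write_sif(((u, v) for u, v in tree.edges), sif_path, interaction="steiner")
    if attr_path is not None:
        with open(attr_path, "w") as fh:
            fh.write("node\trole\tstrand\n")
            for v in sorted(tree.nodes):
                role = "terminal" if v in tree.terminals else "steiner"
                strand = "antisense" if v.endswith("_AS") else "sense"
                fh.write(f"{v}\t{role}\t{strand}\n")


# -- ontology and annotations ----------------------------------------------

def read_obo(path: str | Path) -> nx.DiGraph:
    """Minimal OBO parser: [Term] stanzas with id / name / is_a.

    Returns a DiGraph with child -> parent arcs and a ``name`` attribute
    per node.  Obsolete terms are skipped.
    """
    dag = nx.DiGraph()
    term_id = None
    name = None
    parents: list[str] = []
    obsolete = False
    in_term = False

    def flush():
        if term_id is None or obsolete:
            return
        dag.add_node(term_id, name=name or term_id)
        for p in parents:
            dag.add_edge(term_id, p)

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                if in_term:
                    flush()
                in_term, term_id, name, parents, obsolete = True, None, None, [], False
            elif line.startswith("[") and line.endswith("]"):
                if in_term:
                    flush()
                in_term = False
            elif in_term:
                if line.startswith("id:"):
                    term_id = line[3:].strip()
                elif line.startswith("name:"):
                    name = line[5:].strip()
                elif line.startswith("is_a:"):
                    parents.append(line[5:].strip().split("!")[0].strip())
                elif line == "is_obsolete: true":
                    obsolete = True
    if in_term:
        flush()
    return dag


def read_annotations(path: str | Path, dag: nx.DiGraph | None = None) -> AnnotationMap:
    """Tab-delimited table: gene, GO term[, GO-slim category]."""
    gene2terms: dict[str, set[str]] = {}
    slim: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        if ncol < 2:
            raise ValueError("annotation table needs >= 2 columns")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            gene, term = parts[0], parts[1]
            gene2terms.setdefault(gene, set()).add(term)
            if len(parts) >= 3 and parts[2]:
                slim[term] = parts[2]
    return AnnotationMap(gene2terms, dag or nx.DiGraph(), slim)


# -- results ---------------------------------------------------------------

def write_enrichment(results: list[EnrichmentResult], path: str | Path) -> None:
    """Column layout: term, p, corrected p, k, K, n, N, name, members."""
    with open(path, "w") as fh:
        fh.write("term\tp_value\tp_corrected\tk\tK\tn\tN\tname\tmembers\n")
        for r in results:
            members = "|".join(r.members)
            fh.write(
                f"{r.term}\t{r.p_value:.6g}\t{r.p_corrected:.6g}\t"
                f"{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.name}\t{members}\n"
            )


def write_manifest(config: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
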