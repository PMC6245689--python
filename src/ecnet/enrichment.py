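"""Hypergeometric over-representation analysis on GO / GO-slim terms.

Implements the upper-tail hypergeometric test with Bonferroni or
Benjamini-Hochberg correction, true-path propagation of annotations up
the term DAG, and the differential *revealed-by-AS* comparison: terms
significant for the sense+anti-sense gene set but not for the sense-only
set.  Anti-sense transcripts inherit the annotation of their sense gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "hypergeom_p",
    "enrich",
    "revealed_by_as",
    "propagate",
]

UNKNOWN_TERM = "unknown biological processes"


def _gene_key(gene) -> str:
    """Anti-sense transcripts carry their sense gene's annotation."""
    name = str(gene)
    return name[:-3] if name.endswith("_AS") else name


@dataclass
class AnnotationMap:
    """gene -> GO terms, the term DAG (child -> parent arcs), and the
    term -> GO-slim category map."""

    gene2terms: dict[str, set[str]]
    dag: nx.DiGraph = field(default_factory=nx.DiGraph)
    slim: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dag.number_of_nodes() and not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("GO DAG contains a cycle")

    def terms_of(self, gene, vocabulary: str = "go") -> set[str]:
        terms = self.gene2terms.get(_gene_key(gene), {UNKNOWN_TERM})
        if vocabulary == "go":
            return set(terms)
        if vocabulary == "slim":
            return {self.slim[t] for t in terms if t in self.slim}
        raise ValueError(f"unknown vocabulary {vocabulary!r}")


@dataclass
class EnrichmentResult:
    term: str
    k: int  # sample genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # sample size
    N: int  # universe size
    p_value: float
    p_corrected: float
    members: list[str] = field(default_factory=list)
    name: str = ""


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _correct(pvals: list[float], method: str) -> list[float]:
    if not pvals:
        return []
    if method == "none":
        return list(pvals)
    if method == "bonferroni":
        m = len(pvals)
        return [min(1.0, m * p) for p in pvals]
    if method == "bh":
        return list(multipletests(pvals, method="fdr_bh")[1])
    raise ValueError(f"unknown correction {method!r}")


def enrich(
    genes: set,
    ann: AnnotationMap,
    universe: set,
    vocabulary: str = "go",
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One upper-tail hypergeometric test per term seen in the sample.

    Counts use the (propagated) annotation; correction is applied across
    all tested terms and results come back sorted by corrected p-value.
    """
    genes = {str(g) for g in genes}
    universe = {str(g) for g in universe}
    if not genes <= universe:
        raise ValueError("sample genes must be a subset of the universe")
    if not genes:
        return []

    sample_terms: dict[str, list[str]] = {}
    for g in sorted(genes):
        for t in ann.terms_of(g, vocabulary):
            sample_terms.setdefault(t, []).append(g)
    universe_counts: dict[str, int] = {}
    for g in universe:
        for t in ann.terms_of(g, vocabulary):
            universe_counts[t] = universe_counts.get(t, 0) + 1

    n, N = len(genes), len(universe)
    results = []
    for term, members in sorted(sample_terms.items()):
        k = len(members)
        K = universe_counts[term]
        results.append(
            EnrichmentResult(term, k, K, n, N, hypergeom_p(k, K, n, N), 1.0, members)
        )
    corrected = _correct([r.p_value for r in results], correction)
    for r, pc in zip(results, corrected):
        r.p_corrected = pc
    results.sort(key=lambda r: (r.p_corrected, r.p_value, r.term))
    return results


def significant_terms(results: list[EnrichmentResult], alpha: float = 0.05,
                      corrected: bool = True) -> set[str]:
    key = (lambda r: r.p_corrected) if corrected else (lambda r: r.p_value)
    return {r.term for r in results if key(r) < alpha}


def revealed_by_as(
    set_S: set,
    set_SAS: set,
    ann: AnnotationMap,
    universe: set,
    alpha: float = 0.05,
    vocabulary: str = "go",
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Terms significant for the S+AS gene set but not for the S set."""
    res_S = enrich(set_S, ann, universe, vocabulary, correction, alpha) if set_S else []
    res_SAS = enrich(set_SAS, ann, universe, vocabulary, correction, alpha)
    sig_S = significant_terms(res_S, alpha)
    return [r for r in res_SAS if r.p_corrected < alpha and r.term not in sig_S]


def propagate(ann: AnnotationMap) -> AnnotationMap:
    """True-path rule: annotate every gene to all ancestors of its terms."""
    if ann.dag.number_of_nodes() and not nx.is_directed_acyclic_graph(ann.dag):
        raise ValueError("GO DAG contains a cycle")
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            if term in ann.dag:
                ancestors[term] = nx.descendants(ann.dag, term)  # child->parent arcs
            else:
                ancestors[term] = set()
        return ancestors[term]

    new_map = {
        g: set().union(terms, *(anc(t) for t in terms))
        for g, terms in ann.gene2terms.items()
    }
    return AnnotationMap(new_map, ann.dag, dict(ann.slim))
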