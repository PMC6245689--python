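"""End-to-end workflow: normalize -> DE filter -> MI -> S/SAS inference ->
differential analysis -> Steiner trees -> enrichment."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import differential, enrichment, steiner
from .core_network import ecn_infer, symmetrize
from .datatypes import ExpressionMatrix
from .mi import copula_transform, mi_matrix, significance_mask
from .preprocess import (
    count_couples,
    de_transcripts,
    differential_expression,
    quantile_normalize,
)

log = logging.getLogger("ecnet")

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    accepting_rate: float = 0.05
    alpha_de: float = 0.01
    min_lfc: float = 1.0
    mi_perm: int = 30
    mi_alpha: float = 0.05
    min_subgraph: int = 3
    correction: str = "bonferroni"
    enrich_alpha: float = 0.05
    seed: int = 0
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.accepting_rate <= 1.0:
            raise ValueError("accepting_rate must be in [0, 1]")
        for name in ("alpha_de", "mi_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.mi_perm < 1:
            raise ValueError("mi_perm must be >= 1")
        if self.min_subgraph < 1:
            raise ValueError("min_subgraph must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    de_results: list
    net_S: object
    net_SAS: object
    impacted: set
    motifs: list
    subgraphs: list
    trees: list
    enrichment_S: list = field(default_factory=list)
    enrichment_SAS: list = field(default_factory=list)
    revealed: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        self.code = f"ECNET_{stage.upper()}_FAILED"
        super().__init__(f"[{self.code}] {message}")


def run_pipeline(
    config: RunConfig,
    expr_H: ExpressionMatrix,
    expr_60: ExpressionMatrix,
    annotations: enrichment.AnnotationMap | None = None,
    universe: set | None = None,
) -> PipelineResult:
    """Full differential network analysis on two condition matrices.

    Network inference uses the second condition's expression of the
    DE-filtered transcripts; the S network is inferred from sense rows
    only, the SAS network from sense plus anti-sense rows.
    """
    counts: dict[str, int] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-tag with stage
                raise PipelineError(name, str(exc)) from exc
        return deco

    if config.normalize:
        expr_H = stage("normalize")(lambda: quantile_normalize(expr_H))
        expr_60 = stage("normalize")(lambda: quantile_normalize(expr_60))

    de = stage("de")(
        lambda: differential_expression(expr_H, expr_60, config.alpha_de, config.min_lfc)
    )
    flagged = de_transcripts(de)
    sense_de = [t for t in flagged if t.is_sense]
    anti_de = [t for t in flagged if t.is_antisense]
    counts["de_sense"] = len(sense_de)
    counts["de_antisense"] = len(anti_de)
    counts["de_couples"] = count_couples(flagged)
    counts["de_total"] = len(flagged)
    log.info(
        "DE filter: %d sense, %d anti-sense, %d couples, %d total",
        counts["de_sense"], counts["de_antisense"],
        counts["de_couples"], counts["de_total"],
    )

    sas_expr = expr_60.subset_transcripts(flagged)
    s_expr = sas_expr.sense_only()
    if s_expr.n_transcripts < 2:
        raise PipelineError("mi", "fewer than 2 sense DE transcripts")

    def infer(expr, seed_offset):
        ct = copula_transform(expr)
        mi = mi_matrix(ct)
        return ecn_infer(
            significance_mask(
                mi, ct, config.mi_perm, config.mi_alpha,
                seed=config.seed + seed_offset,
            ),
            config.accepting_rate,
        )

    net_S = stage("infer_s")(lambda: infer(s_expr, 1))
    net_SAS = stage("infer_sas")(lambda: infer(sas_expr, 2))
    counts["edges_S"] = net_S.n_edges()
    counts["edges_SAS"] = net_SAS.n_edges()

    impacted = stage("differential")(
        lambda: differential.find_as_impacted(net_S, net_SAS)
    )
    counts["as_impacted"] = len(impacted)
    motifs = [
        differential.build_change_motif(g, net_S, net_SAS, enlarge=True)
        for g in sorted(impacted)
    ]
    counts["change_motifs"] = len(motifs)

    subgraphs = stage("subgraphs")(
        lambda: differential.as_impacted_subgraphs(net_S, impacted, config.min_subgraph)
    )
    counts["as_subgraphs"] = len(subgraphs)
    log.info(
        "differential: %d AS-impacted genes, %d sub-graphs (>=%d nodes)",
        counts["as_impacted"], counts["as_subgraphs"], config.min_subgraph,
    )

    sas_graph = symmetrize(net_SAS, "union").to_networkx()
    trees = []
    for sg in subgraphs:
        terms = {str(t) for t in sg.members}
        try:
            tree = steiner.steiner_sp_approx(sas_graph, terms, seed=config.seed)
        except steiner.DisconnectedTerminalsError:
            tree = None
        trees.append(tree)
    counts["steiner_trees"] = sum(1 for t in trees if t is not None)

    result = PipelineResult(
        de, net_S, net_SAS, impacted, motifs, subgraphs, trees, counts=counts
    )

    if annotations is not None:
        ann = enrichment.propagate(annotations)
        if universe is None:
            universe = {str(t) for t in expr_60.transcripts}
        s_genes = {str(t) for t in sense_de}
        sas_genes = {str(t) for t in flagged}
        result.enrichment_S = enrichment.enrich(
            s_genes, ann, universe, "go", config.correction, config.enrich_alpha
        )
        result.enrichment_SAS = enrichment.enrich(
            sas_genes, ann, universe, "go", config.correction, config.enrich_alpha
        )
        result.revealed = enrichment.revealed_by_as(
            s_genes, sas_genes, ann, universe, config.enrich_alpha,
            "go", config.correction,
        )
        counts["revealed_terms"] = len(result.revealed)
    return result
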