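"""End-to-end orchestration: correlation -> clustering -> annotation ->
reaction network -> pathway predictions, with one config object."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import networkx as nx
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import cluster as cluster_mod
from . import correlate as correlate_mod
from . import predict as predict_mod
from .core_data import (
    ExpressionMatrix,
    FeatureTable,
    MetaboliteRecord,
    ReactionRule,
    TranscriptAnnotation,
    ValidationError,
    align_samples,
)
from .rules import build_transition_index

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable parameters of a full run; defaults are the package defaults.

    min_abs_r: minimum |Pearson r| for an edge to enter the network.
    decay_rates: mutual-rank decay rates, one network per rate.
    weight_cutoff: minimum decay weight retained in a network.
    ppm: mass-accuracy tolerance for structure annotation (parts per million).
    tier: rule-enzyme association tier (strict | medium | loose).
    predict_dr: decay rate whose network feeds clustering and prediction.
    ghost_mode: ghost-intermediate generation (off | auto | always).
    """

    min_abs_r: float = 0.1
    decay_rates: tuple[int, ...] = (5, 10, 25, 50)
    weight_cutoff: float = 0.01
    ppm: float = 20.0
    tier: str = "loose"
    taxa: tuple[str, ...] | None = None
    predict_dr: int = 10
    ghost_mode: str = "auto"
    rounds: int = 1
    rescale: bool = True
    cluster_restrict: bool = True
    match_tol_da: float = 0.002
    min_size: int = 3
    penalty: float = 2.0
    overlap_threshold: float = 0.8
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["decay_rates"] = list(self.decay_rates)
        data["taxa"] = None if self.taxa is None else list(self.taxa)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data.get("decay_rates") is not None:
            data["decay_rates"] = tuple(data["decay_rates"])
        if data.get("taxa") is not None:
            data["taxa"] = tuple(data["taxa"])
        return cls(**data)


@dataclass
class PipelineResult:
    features: FeatureTable
    expression: ExpressionMatrix
    edges: pd.DataFrame
    networks: dict[int, pd.DataFrame]
    clusters: list
    candidates: pd.DataFrame
    nodes: list
    reaction_edges: pd.DataFrame
    graph: nx.MultiDiGraph
    pathways: dict[str, tuple]

    def summary(self) -> dict:
        return {
            "n_features": len(self.features),
            "n_transcripts": len(self.expression),
            "n_correlation_edges": len(self.edges),
            "network_sizes": {dr: len(df) for dr, df in self.networks.items()},
            "n_clusters": len(self.clusters),
            "n_structure_candidates": len(self.candidates),
            "n_nodes": len(self.nodes),
            "n_reaction_edges": len(self.reaction_edges),
            "n_pathway_roots": len(self.pathways),
        }


def tier_filter_rules(rules: list[ReactionRule], tier: str, taxa=None) -> list[ReactionRule]:
    """Restrict in-memory rules to associations at (or above) a tier and,
    optionally, to a taxon list; rules left without associations drop out."""
    from dataclasses import replace

    from .core_data import _tier_levels

    levels = _tier_levels(tier)
    out = []
    for rule in rules:
        kept = tuple(
            a
            for a in rule.enzyme_associations
            if a.tier in levels and (taxa is None or (a.taxon is not None and a.taxon in taxa))
        )
        if kept:
            out.append(replace(rule, enzyme_associations=kept))
    return out


def run_pipeline(
    features: FeatureTable,
    expression: ExpressionMatrix,
    rules: list[ReactionRule],
    adducts,
    metabolite_db: list[MetaboliteRecord],
    annotations: list[TranscriptAnnotation],
    config: RunConfig | None = None,
    roots: list[str] | None = None,
) -> PipelineResult:
    """Full run. ``roots`` are feature ids (or node ids) to anchor pathway
    extraction; by default every measured node that has at least one
    outgoing reaction edge and no incoming one (a source metabolite)."""
    cfg = config or RunConfig()
    features, expression = align_samples(features, expression)
    feats_c, expr_c = features, expression
    if cfg.rescale:
        feats_c = correlate_mod.mad_rescale(features)
        expr_c = correlate_mod.mad_rescale(expression)
    edges = correlate_mod.correlate_pairs(expr_c, feats_c, min_abs_r=cfg.min_abs_r)
    edges = correlate_mod.mutual_rank(edges)
    networks = correlate_mod.decay_weights(
        edges, decay_rates=cfg.decay_rates, cutoff=cfg.weight_cutoff
    )
    if cfg.predict_dr not in networks:
        raise ValidationError(
            f"predict_dr {cfg.predict_dr} not among decay rates {sorted(networks)}"
        )
    net = networks[cfg.predict_dr]
    graph = cluster_mod.network_graph(net)
    clusters = cluster_mod.detect_clusters(
        graph,
        min_size=cfg.min_size,
        penalty=cfg.penalty,
        overlap_threshold=cfg.overlap_threshold,
        decay_rate=cfg.predict_dr,
    )
    clusters = cluster_mod.merge_shared_feature_clusters(clusters)

    candidates = annotate_mod.annotate_features(
        features, adducts=adducts, db=metabolite_db, ppm=cfg.ppm
    )
    active_rules = tier_filter_rules(rules, cfg.tier, cfg.taxa)
    index = build_transition_index(active_rules)
    nodes = predict_mod.feature_nodes(
        features, candidates, fallback_adducts=tuple(adducts)[:1]
    )
    pairs = predict_mod.match_mass_pairs(nodes, index, tol_da=cfg.match_tol_da)
    pairs, ghosts = predict_mod.insert_ghosts(
        pairs, nodes, index, mode=cfg.ghost_mode, tol_da=cfg.match_tol_da
    )
    reaction_edges = predict_mod.attach_enzyme_support(
        pairs,
        net,
        annotations,
        {r.rule_id: r for r in active_rules},
        clusters=clusters,
        cluster_restrict=cfg.cluster_restrict,
    )
    g = predict_mod.build_network(reaction_edges, nodes + ghosts)
    if cfg.rounds > 1:
        g = predict_mod.iterate_prediction(
            g, nodes + ghosts, active_rules, rounds=cfg.rounds - 1,
            tol_da=cfg.match_tol_da,
        )

    if roots is None:
        root_nodes = predict_mod.default_roots(g)
    else:
        root_nodes = []
        for r in roots:
            if r in g:
                root_nodes.append(r)
            else:
                matches = sorted(
                    n for n in g if g.nodes[n].get("source_feature") == r
                )
                if not matches:
                    raise ValidationError(f"root {r!r} matches no network node")
                root_nodes.extend(matches)
    pathways = {}
    for root in root_nodes:
        try:
            pathways[root] = predict_mod.predict_pathways(g, root)
        except ValidationError:
            continue
    return PipelineResult(
        features=features,
        expression=expression,
        edges=edges,
        networks=networks,
        clusters=clusters,
        candidates=candidates,
        nodes=nodes + ghosts,
        reaction_edges=reaction_edges,
        graph=g,
        pathways=pathways,
    )


def pathways_to_frame(pathways: dict[str, tuple]) -> pd.DataFrame:
    """Flatten pathway predictions to a per-edge table."""
    rows = []
    for root, (forward, reverse) in sorted(pathways.items()):
        for mode, pw in (("forward", forward), ("reverse", reverse)):
            for step, (u, v, rule_id) in enumerate(pw.edges):
                rows.append(
                    {
                        "root": root,
                        "mode": mode,
                        "step": step,
                        "substrate_node": u,
                        "product_node": v,
                        "rule_id": rule_id,
                        "path_length": len(pw),
                        "total_support": pw.total_support,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "root", "mode", "step", "substrate_node", "product_node",
            "rule_id", "path_length", "total_support",
        ],
    )
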