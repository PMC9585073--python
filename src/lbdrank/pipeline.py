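"""Configuration-driven orchestration of the full closed-discovery run.

Stages: ingest triples -> build graph -> ComplEx embeddings -> triple
vectors -> autoencoder -> triple scores -> path enumeration per target and
depth -> ranking -> top-percentile selection -> optional ranking-agreement
report.  Every artifact is written to the output directory together with a
manifest (config hash, seeds, per-stage row counts) sufficient to
reproduce the run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import kg_core, paths as path_engine, rbo as rbo_mod, scorer, synthetic
from .embedding import ComplExConfig, EmbeddingTable, save_embeddings, train_complex
from .kg_core import KnowledgeGraph, ValidationError
from .scorer import AutoencoderConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    triples: str | None = None            # triples TSV
    node_types: str | None = None         # node-type TSV
    hetionet_json: str | None = None      # alternative input: hetionet-style JSON
    use_glyburide_fixture: bool = False   # alternative input: built-in worked example
    permissive_relations: bool = True
    default_entity_type: str | None = None
    sources: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    depths: list[int] = field(default_factory=lambda: [2, 3])
    percentile: float = 5.0
    rbo_p: float = 0.9
    reference_ranking: str | None = None  # TSV of (source, rank, path identifier)
    embedding: dict = field(default_factory=dict)
    autoencoder: dict = field(default_factory=dict)
    seed: int = 0
    path_cap: int | None = None
    out_dir: str = "run_out"

    def __post_init__(self) -> None:
        if not set(self.depths) <= {1, 2, 3, 4}:
            raise ValidationError(f"depths must be within {{1,2,3,4}}, got {self.depths}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate_inputs(self) -> None:
        for p in (self.triples, self.node_types, self.hetionet_json, self.reference_ranking):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured input does not exist: {p}")
        if not (self.triples or self.hetionet_json or self.use_glyburide_fixture):
            raise ValidationError("no input source configured")


def _load_graph(config: RunConfig) -> KnowledgeGraph:
    if config.use_glyburide_fixture:
        return synthetic.glyburide_fixture()
    if config.hetionet_json:
        return kg_core.read_hetionet_json(config.hetionet_json)
    triples = kg_core.read_triples(config.triples, permissive=config.permissive_relations)
    node_types = kg_core.read_node_types(config.node_types) if config.node_types else {}
    return kg_core.build_graph(triples, node_types, default_type=config.default_entity_type)


def run_pipeline(config: RunConfig, theta_override=None) -> dict:
    """Execute every stage and return the run manifest.

    ``theta_override`` optionally replaces the embed/score stages with a
    fixed theta lookup (used for stub-scorer runs and debugging).
    """
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    t0 = time.perf_counter()
    graph = _load_graph(config)
    stage("graph", nodes=graph.num_nodes, edges=graph.num_edges,
          seconds=round(time.perf_counter() - t0, 3))
    kg_core.export_graph(graph, out / "nodes.tsv", out / "edges.tsv")

    if theta_override is None:
        t0 = time.perf_counter()
        emb_cfg = ComplExConfig(**{"seed": config.seed, **config.embedding})
        table = train_complex(graph, emb_cfg)
        save_embeddings(out / "embeddings.tsv", table)
        stage("embed", k=table.k, entities=len(table.entity_embeddings),
              relations=len(table.relation_embeddings),
              final_loss=table.loss_log[-1] if table.loss_log else None,
              seed=emb_cfg.seed, seconds=round(time.perf_counter() - t0, 3))

        t0 = time.perf_counter()
        vectors = scorer.build_triple_vectors(table, graph)
        ae_cfg = AutoencoderConfig(**{"seed": config.seed, **config.autoencoder})
        model = scorer.train_autoencoder(vectors, ae_cfg)
        weights = scorer.extract_scoring_weights(model)
        thetas = scorer.score_triples(vectors, weights)
        scorer.write_scored_triples(out / "scored_triples.tsv", thetas)
        stage("score_triples", n=len(thetas), final_mse=model.loss_log[-1] if model.loss_log else None,
              seed=ae_cfg.seed, seconds=round(time.perf_counter() - t0, 3))
    else:
        thetas = dict(theta_override)
        scorer.write_scored_triples(out / "scored_triples.tsv", thetas)
        stage("score_triples", n=len(thetas), stub=True)

    t0 = time.perf_counter()
    all_paths = []
    per_cell = {}
    for target in config.targets:
        for depth in config.depths:
            found = path_engine.enumerate_paths(
                graph, config.sources, target, depth, cap=config.path_cap
            )
            per_cell[f"{target}@d{depth}"] = len(found)
            all_paths.extend(found)
    stage("paths", total=len(all_paths), per_cell=per_cell,
          seconds=round(time.perf_counter() - t0, 3))

    ranking = path_engine.score_and_rank(all_paths, thetas)
    path_engine.write_ranked_paths(out / "ranked_paths.tsv", ranking)
    top = path_engine.select_top_percentile(ranking, config.percentile)
    path_engine.write_ranked_paths(out / "top_percentile.tsv", path_engine.Ranking(list(top)))
    stage("rank", ranked=len(ranking), top=len(top), percentile=config.percentile)

    if config.reference_ranking:
        refs = rbo_mod.read_reference_ranking(config.reference_ranking)
        by_source: dict[str, list] = {}
        for sp in ranking:
            by_source.setdefault(sp.path.nodes[0], []).append(sp.path.render())
        pairs = []
        for source, ref in sorted(refs.items()):
            ours = by_source.get(source)
            if ours is None:
                logger.warning("no produced ranking for reference source %r", source)
                continue
            pairs.append((source, rbo_mod.RankedList(tuple(ours), source), ref, config.depths[0]))
        if pairs:
            report = rbo_mod.agreement_report(pairs, p=config.rbo_p)
            rbo_mod.write_agreement_report(out / "agreement.csv", report)
            stage("rbo", pairs=len(pairs), mean_pct=round(report.mean_pct, 2), p=config.rbo_p)

    manifest["complete"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
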