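"""Seeded generators for typed knowledge graphs, toy corpora, and the
Glyburide worked-example fixture.

The synthetic knowledge graph emulates the structure of a
literature-derived biomedical network: nodes of the seven entity types,
edges drawn from the 28-predicate vocabulary, a skewed (Zipf-like) degree
distribution, and per-relation type signatures — each predicate links a
small set of head entity types to a small set of tail entity types, the
way "treats" links compounds to phenotypes.  Held-out true edges follow
the same signature and popularity pattern, so they are statistically
distinguishable from uniform corruptions — the property a
link-prediction embedding is expected to exploit.  Planted
source-to-target paths make path enumeration testable against a known
manifest.  Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kg_core import (
    ENTITY_TYPES,
    RELATION_VOCABULARY,
    EntityRecord,
    KnowledgeGraph,
    Triple,
    ValidationError,
)
from .ner import Dictionary, EntityMention

_DEFAULT_NODE_COUNTS = {
    "phenotype": 50,
    "compound": 50,
    "gene": 40,
    "protein": 25,
    "biological_process": 15,
    "molecular_function": 10,
    "rna": 10,
}


@dataclass
class SyntheticKGConfig:
    node_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_NODE_COUNTS))
    relations: tuple[str, ...] = RELATION_VOCABULARY
    edge_count: int = 1000
    degree_skew: float = 1.5          # endpoint-sampling weight ~ rank^(-skew)
    types_per_relation: int = 1       # head/tail entity types in each relation's signature
    source_label: str = "source_compound"
    target_label: str = "target_phenotype"
    planted_paths: dict[int, int] = field(default_factory=dict)   # depth -> count
    held_out_edges: int = 0           # extra same-distribution triples kept out of the graph
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.node_counts.values()) or self.edge_count < 1:
            raise ValidationError("node and edge counts must be positive")
        if not set(self.node_counts) <= ENTITY_TYPES:
            raise ValidationError(f"unknown entity types: {set(self.node_counts) - ENTITY_TYPES}")
        if self.types_per_relation < 1 or not self.relations:
            raise ValidationError("need >=1 type per relation signature and >=1 relation")


def generate_kg(config: SyntheticKGConfig) -> tuple[KnowledgeGraph, dict]:
    """Generate a typed multigraph plus a manifest of planted structure.

    The manifest records node types, planted paths (as node/relation
    sequences), and held-out triples drawn from the same generative
    pattern as the graph's edges but excluded from it.
    """
    rng = np.random.default_rng(config.seed)
    graph = KnowledgeGraph()

    node_ids: list[str] = []
    node_types: dict[str, str] = {}
    for etype in sorted(config.node_counts):
        for i in range(config.node_counts[etype]):
            node_id = f"{etype}_{i:03d}"
            node_ids.append(node_id)
            node_types[node_id] = etype
    node_types[config.source_label] = "compound"
    node_types[config.target_label] = "phenotype"
    for node_id in [*node_ids, config.source_label, config.target_label]:
        graph.add_node(EntityRecord(node_id, node_types[node_id]))

    n = len(node_ids)
    types_present = sorted({node_types[v] for v in node_ids})
    by_type: dict[str, list[str]] = {et: [] for et in types_present}
    for node in node_ids:
        by_type[node_types[node]].append(node)
    # each relation's type signature: which head types link to which tail types
    tpr = min(config.types_per_relation, len(types_present))
    signature = {
        r: (
            sorted(rng.choice(types_present, size=tpr, replace=False)),
            sorted(rng.choice(types_present, size=tpr, replace=False)),
        )
        for r in config.relations
    }
    # Zipf-like popularity over a seeded random ordering of the nodes
    ranks = rng.permutation(n) + 1
    popularity = {node: float(rk) ** (-config.degree_skew) for node, rk in zip(node_ids, ranks)}

    def weighted_choice(pool: list[str]) -> str:
        w = np.array([popularity[v] for v in pool])
        return pool[rng.choice(len(pool), p=w / w.sum())]

    def sample_pattern_triple() -> Triple | None:
        relation = config.relations[rng.integers(0, len(config.relations))]
        head_types, tail_types = signature[relation]
        head = weighted_choice([v for et in head_types for v in by_type[et]])
        tail = weighted_choice([v for et in tail_types for v in by_type[et]])
        if tail == head:
            return None
        return Triple(head, relation, tail)

    # planted source -> ... -> target paths, one set of intermediates per path
    manifest_paths: list[dict] = []
    planted_keys: set[tuple[str, str, str]] = set()
    for depth in sorted(config.planted_paths):
        count = config.planted_paths[depth]
        if depth < 1 or depth > 4:
            raise ValidationError(f"planted path depth {depth} outside 1..4")
        if count < 0 or (depth > 1 and count * (depth - 1) > n):
            raise ValidationError(f"cannot plant {count} node-disjoint paths of depth {depth}")
        if depth == 1 and count > len(config.relations):
            raise ValidationError("depth-1 planted paths are limited by the relation vocabulary")
        chosen = rng.choice(n, size=count * max(depth - 1, 0), replace=False) if depth > 1 else []
        for i in range(count):
            inter = [node_ids[j] for j in chosen[i * (depth - 1) : (i + 1) * (depth - 1)]]
            nodes = [config.source_label, *inter, config.target_label]
            rels = (
                [config.relations[i]]
                if depth == 1
                else [config.relations[rng.integers(0, len(config.relations))] for _ in range(depth)]
            )
            for a, b, r in zip(nodes[:-1], nodes[1:], rels):
                graph.add_triple(Triple(a, r, b))
                planted_keys.add((a, r, b))
            manifest_paths.append({"depth": depth, "nodes": nodes, "relations": rels})

    if len(planted_keys) > config.edge_count:
        raise ValidationError(
            f"planted paths need {len(planted_keys)} edges, over the budget of {config.edge_count}"
        )

    # background edges from the community pattern, up to the edge budget
    attempts = 0
    while graph.num_edges < config.edge_count:
        attempts += 1
        if attempts > 100 * config.edge_count:
            raise ValidationError("edge budget infeasible under the community pattern")
        t = sample_pattern_triple()
        if t is None or t.key in graph.edges:
            continue
        graph.add_triple(t)

    held_out: list[Triple] = []
    attempts = 0
    while len(held_out) < config.held_out_edges:
        attempts += 1
        if attempts > 100 * max(config.held_out_edges, 1):
            raise ValidationError("held-out edge budget infeasible")
        t = sample_pattern_triple()
        if t is None or t.key in graph.edges or any(t.key == h.key for h in held_out):
            continue
        held_out.append(t)

    manifest = {
        "node_types": node_types,
        "relation_signatures": signature,
        "planted_paths": manifest_paths,
        "held_out": [h.key for h in held_out],
        "seed": config.seed,
    }
    return graph, manifest


def corrupt_triples(
    graph: KnowledgeGraph,
    triples: list[tuple[str, str, str]],
    seed: int,
) -> list[tuple[str, str, str]]:
    """Uniformly corrupt the head or tail of each triple (coin flip),
    avoiding observed edge keys and self-loops."""
    rng = np.random.default_rng(seed)
    entities = sorted(graph.nodes)
    out: list[tuple[str, str, str]] = []
    for h, r, t in triples:
        while True:
            other = entities[rng.integers(0, len(entities))]
            key = (other, r, t) if rng.random() < 0.5 else (h, r, other)
            if key[0] != key[2] and key not in graph.edges:
                out.append(key)
                break
    return out


# ---------------------------------------------------------------------------
# The Glyburide worked example: 14 depth-2 paths to type 2 diabetes mellitus
# ---------------------------------------------------------------------------

# (intermediate, its type, relation source->intermediate, relation intermediate->target),
# in published ranking order of the produced paths.
_GLYBURIDE_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("gestational_diabetes", "phenotype", "treats", "resembles"),
    ("tolazamide", "compound", "resembles", "treats"),
    ("abcc8", "gene", "binds", "associates"),
    ("kcnj11", "gene", "binds", "associates"),
    ("glipizide", "compound", "resembles", "treats"),
    ("chlorpropamide", "compound", "resembles", "treats"),
    ("glimepiride", "compound", "resembles", "treats"),
    ("abcc2", "gene", "binds", "associates"),
    ("gliclazide", "compound", "resembles", "treats"),
    ("cpt1a", "gene", "binds", "associates"),
    ("cyp3a4", "gene", "binds", "associates"),
    ("alb", "gene", "binds", "associates"),
    ("vegfa", "gene", "downregulates", "associates"),
    ("hif1a", "gene", "downregulates", "associates"),
)

#: Reference ranking of the same 14 paths (position i holds the reference
#: rank of the i-th path above).
_GLYBURIDE_REFERENCE_RANKS: tuple[int, ...] = (1, 3, 8, 9, 5, 6, 2, 10, 4, 7, 11, 12, 14, 13)

GLYBURIDE_SOURCE = "glyburide"
GLYBURIDE_TARGET = "type_2_diabetes_mellitus"


def glyburide_fixture() -> KnowledgeGraph:
    """The published Glyburide / type-2-diabetes-mellitus subgraph.

    16 nodes and 28 edges forming 14 depth-2 paths through distinct
    intermediates; relations (treats, resembles, binds, associates,
    downregulates) are Hetionet-style and admitted permissively.  Edge
    direction follows the reading order of each path segment.
    """
    graph = KnowledgeGraph()
    graph.add_node(EntityRecord(GLYBURIDE_SOURCE, "compound"))
    graph.add_node(EntityRecord(GLYBURIDE_TARGET, "phenotype"))
    for inter, etype, r1, r2 in _GLYBURIDE_ROWS:
        graph.add_node(EntityRecord(inter, etype))
        graph.add_triple(Triple(GLYBURIDE_SOURCE, r1, inter))
        graph.add_triple(Triple(inter, r2, GLYBURIDE_TARGET))
    return graph


def glyburide_reference_rankings() -> tuple[list[str], list[str]]:
    """The two published orderings of the 14 Glyburide paths.

    Returns (produced-ranking order, reference-ranking order) as rendered
    path identifiers, for ranking-agreement evaluation.
    """
    rendered = [
        f"{GLYBURIDE_SOURCE}—[{r1}]—{inter}—[{r2}]—{GLYBURIDE_TARGET}"
        for inter, _etype, r1, r2 in _GLYBURIDE_ROWS
    ]
    by_reference = [
        ident for _, ident in sorted(zip(_GLYBURIDE_REFERENCE_RANKS, rendered))
    ]
    return rendered, by_reference


def xanthium_path_totals() -> "pd.DataFrame":
    """Published per-target path totals (depths 2 and 3) for the Xanthium
    compounds-to-diabetes run, as input data for aggregation checks."""
    import pandas as pd

    data = {
        "type_1_diabetes": (2314, 693158),
        "type_2_diabetes": (3130, 850239),
        "diabetes_mellitus": (4586, 1186887),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=[2, 3]).rename_axis("target")


# ---------------------------------------------------------------------------
# Toy sentence corpus with planted entity mentions
# ---------------------------------------------------------------------------

_FILLER_OPENERS = (
    "recent studies reported that",
    "we observed that",
    "in treated patients,",
    "preliminary evidence suggests",
    "the assay indicated that",
)
_FILLER_MIDDLES = (
    "was elevated alongside",
    "strongly modulates",
    "showed no interaction with",
    "co-occurred with",
    "may regulate",
)
_FILLER_CLOSERS = (
    "in the cohort.",
    "under fasting conditions.",
    "after repeated dosing.",
    "in murine models.",
    "across replicates.",
)


def generate_corpus(
    dictionary: Dictionary, n_sentences: int, seed: int = 0
) -> tuple[list[dict], list[EntityMention]]:
    """Generate JSONL-ready sentence records with 0-4 planted dictionary terms.

    Returns (records, ground-truth mentions); each record is
    {"doc_id", "sentence_id", "text"}.  Surface forms are the dictionary
    terms with underscores rendered as spaces, so the extractor's
    normalization recovers the canonical ids exactly.
    """
    if n_sentences <= 0:
        raise ValidationError(f"n_sentences must be positive, got {n_sentences}")
    rng = np.random.default_rng(seed)
    terms = sorted(dictionary.entries)
    records: list[dict] = []
    truth: list[EntityMention] = []
    for i in range(n_sentences):
        sentence_id = f"s{i:05d}"
        n_terms = int(rng.integers(0, 5))
        chosen = (
            [terms[j] for j in rng.choice(len(terms), size=min(n_terms, len(terms)), replace=False)]
            if n_terms
            else []
        )
        pieces: list[str] = [_FILLER_OPENERS[rng.integers(0, len(_FILLER_OPENERS))]]
        cursor = len(pieces[0])
        for j, term in enumerate(chosen):
            surface = term.replace("_", " ")
            pieces.append(" ")
            cursor += 1
            node_id, etype = dictionary.entries[term]
            truth.append(EntityMention(sentence_id, cursor, cursor + len(surface), node_id, etype))
            pieces.append(surface)
            cursor += len(surface)
            filler = (
                _FILLER_MIDDLES[rng.integers(0, len(_FILLER_MIDDLES))]
                if j < len(chosen) - 1
                else _FILLER_CLOSERS[rng.integers(0, len(_FILLER_CLOSERS))]
            )
            pieces.append(" " + filler)
            cursor += 1 + len(filler)
        if not chosen:
            closer = _FILLER_CLOSERS[rng.integers(0, len(_FILLER_CLOSERS))]
            pieces.append(" nothing notable was recorded " + closer)
        records.append(
            {"doc_id": f"d{i // 10:04d}", "sentence_id": sentence_id, "text": "".join(pieces)}
        )
    return records, truth
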