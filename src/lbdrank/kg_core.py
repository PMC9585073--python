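"""Core domain types for the biomedical knowledge graph.

Entities are normalized name strings with one of seven closed types
(phenotype, compound, gene, protein, biological process, molecular
function, RNA).  Assertions are (head, relation, tail) triples carrying an
aggregated sentence-level evidence count.  The relation vocabulary is the
closed 28-predicate set produced by the relation-classification stage;
a permissive mode admits out-of-vocabulary labels so that external
networks (e.g. a Hetionet-style JSON export, whose edge kinds such as
"treats" or "binds" are not in the 28-predicate set) can be imported.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The seven closed entity types.
ENTITY_TYPES: frozenset[str] = frozenset(
    {
        "phenotype",
        "compound",
        "gene",
        "protein",
        "biological_process",
        "molecular_function",
        "rna",
    }
)

#: The closed 28-predicate relation vocabulary (normalized form).
RELATION_VOCABULARY: tuple[str, ...] = (
    "process_of",
    "part_of",
    "location_of",
    "diagnoses",
    "interacts_with",
    "treats",
    "coexists_with",
    "is_a",
    "uses",
    "precedes",
    "associated_with",
    "causes",
    "affects",
    "administered_to",
    "disrupts",
    "occurs_in",
    "complicates",
    "inhibits",
    "stimulates",
    "augments",
    "compared_with",
    "prevents",
    "method_of",
    "neg_interacts_with",
    "neg_affects",
    "produces",
    "manifestation_of",
    "higher_than",
)

_RELATION_SET = frozenset(RELATION_VOCABULARY)

_WS_HYPHEN = re.compile(r"[\s\-]+")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def normalize_name(name: str) -> str:
    """Normalize an entity name: lowercase, spaces/hyphens -> underscore.

    Commas are retained ("1,3-di-O-caffeoylquinic acid" ->
    "1,3_di_o_caffeoylquinic_acid").
    """
    norm = _WS_HYPHEN.sub("_", name.strip()).lower()
    norm = re.sub(r"_+", "_", norm).strip("_")
    return norm


def normalize_relation(label: str) -> str:
    """Normalize a relation label: lowercase, whitespace -> underscore."""
    return _WS_HYPHEN.sub("_", label.strip()).lower()


@dataclass(frozen=True)
class EntityRecord:
    """A typed graph node: normalized name plus one of the 7 entity types."""

    node_id: str
    entity_type: str

    def __post_init__(self) -> None:
        if not self.node_id or re.search(r"\s", self.node_id):
            raise ValidationError(f"invalid node_id: {self.node_id!r}")
        if self.node_id != self.node_id.lower():
            raise ValidationError(f"node_id must be lowercase: {self.node_id!r}")
        if self.entity_type not in ENTITY_TYPES:
            raise ValidationError(
                f"entity_type {self.entity_type!r} not in {sorted(ENTITY_TYPES)}"
            )


def validate_relation(label: str, permissive: bool = False) -> str:
    norm = normalize_relation(label)
    if not permissive and norm not in _RELATION_SET:
        raise ValidationError(f"relation {label!r} not in the 28-predicate vocabulary")
    return norm


@dataclass
class Triple:
    """One (head, relation, tail) assertion with aggregated evidence count."""

    head: str
    relation: str
    tail: str
    count: int = 1
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.head == self.tail:
            raise ValidationError(f"self-loop rejected: {self.head!r}")
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.head, self.relation, self.tail)


class KnowledgeGraph:
    """Typed multigraph over entities with relation-labeled edges.

    Edges are keyed by (head, relation, tail); re-ingesting a duplicate key
    increments its evidence count instead of adding a parallel edge.  An
    adjacency index supports neighbor lookup regardless of stored edge
    direction, which path traversal relies on.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, EntityRecord] = {}
        self.edges: dict[tuple[str, str, str], Triple] = {}
        self._adj: dict[str, list[tuple[str, str, str]]] = {}

    # -- construction -------------------------------------------------

    def add_node(self, record: EntityRecord) -> None:
        existing = self.nodes.get(record.node_id)
        if existing is not None and existing.entity_type != record.entity_type:
            raise ValidationError(
                f"conflicting types for {record.node_id!r}: "
                f"{existing.entity_type} vs {record.entity_type}"
            )
        self.nodes[record.node_id] = record
        self._adj.setdefault(record.node_id, [])

    def add_triple(self, triple: Triple) -> None:
        for endpoint in (triple.head, triple.tail):
            if endpoint not in self.nodes:
                raise ValidationError(f"endpoint {endpoint!r} not a known node")
        existing = self.edges.get(triple.key)
        if existing is not None:
            existing.count += triple.count
            existing.provenance = existing.provenance + tuple(
                p for p in triple.provenance if p not in existing.provenance
            )
            return
        self.edges[triple.key] = Triple(
            triple.head, triple.relation, triple.tail, triple.count, tuple(triple.provenance)
        )
        self._adj[triple.head].append(triple.key)
        self._adj[triple.tail].append(triple.key)

    # -- queries -------------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def incident(self, node_id: str) -> list[tuple[str, str, str]]:
        """Edge keys touching ``node_id`` in either stored direction."""
        return list(self._adj.get(node_id, ()))

    def neighbors(self, node_id: str) -> list[tuple[str, str, str, str, bool]]:
        """(other, head, relation, tail, forward) for each incident edge.

        ``forward`` is True when traversal from ``node_id`` follows the
        stored head->tail direction.
        """
        out = []
        for h, r, t in self._adj.get(node_id, ()):
            if h == node_id:
                out.append((t, h, r, t, True))
            else:
                out.append((h, h, r, t, False))
        return out

    def relation_labels(self) -> list[str]:
        return sorted({r for (_, r, _) in self.edges})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.nodes == other.nodes and {
            k: (v.count, v.provenance) for k, v in self.edges.items()
        } == {k: (v.count, v.provenance) for k, v in other.edges.items()}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_triples(path: str | Path, permissive: bool = False) -> list[Triple]:
    """Read a triples TSV: head, relation, tail, [count], [doc_ids].

    '#'-prefixed lines are comments.  Node names and relation labels are
    normalized on read.  Rows whose head equals tail after normalization are
    dropped with a warning; out-of-vocabulary relations raise unless
    ``permissive``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    triples: list[Triple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(cols)}"
                )
            head = normalize_name(cols[0])
            relation = validate_relation(cols[1], permissive=permissive)
            tail = normalize_name(cols[2])
            if head == tail:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, head)
                continue
            count = int(cols[3]) if len(cols) > 3 and cols[3].strip() else 1
            provenance: tuple[str, ...] = ()
            if len(cols) > 4 and cols[4].strip():
                provenance = tuple(cols[4].split(","))
            triples.append(Triple(head, relation, tail, count, provenance))
    return triples


def write_triples(path: str | Path, triples: Iterable[Triple]) -> None:
    with open(path, "w") as fh:
        fh.write("# head\trelation\ttail\tcount\tdoc_ids\n")
        for t in triples:
            fh.write(
                f"{t.head}\t{t.relation}\t{t.tail}\t{t.count}\t{','.join(t.provenance)}\n"
            )


def read_node_types(path: str | Path) -> dict[str, str]:
    """Read a node-type TSV: node_id, entity_type."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    types: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            types[normalize_name(cols[0])] = cols[1].strip().lower()
    return types


def write_node_types(path: str | Path, node_types: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("# node_id\tentity_type\n")
        for node_id in sorted(node_types):
            fh.write(f"{node_id}\t{node_types[node_id]}\n")


def build_graph(
    triples: Sequence[Triple],
    node_types: Mapping[str, str],
    default_type: str | None = None,
) -> KnowledgeGraph:
    """Assemble a KnowledgeGraph, merging duplicate (head, relation, tail) keys.

    Every endpoint must be typed in ``node_types`` unless ``default_type``
    supplies a fallback; duplicate keys merge with summed counts, so the
    result is independent of input order.
    """
    graph = KnowledgeGraph()
    missing = sorted(
        {
            n
            for t in triples
            for n in (t.head, t.tail)
            if n not in node_types and default_type is None
        }
    )
    if missing:
        raise ValidationError(f"nodes without a type and no default policy: {missing}")
    for t in triples:
        for endpoint in (t.head, t.tail):
            etype = node_types.get(endpoint, default_type)
            graph.add_node(EntityRecord(endpoint, etype))
        graph.add_triple(t)
    return graph


def schema_summary(graph: KnowledgeGraph, weighted: bool = False) -> pd.DataFrame:
    """Per-(head_type, relation, tail_type) counts, sorted descending.

    With ``weighted`` the evidence counts are summed; otherwise distinct
    edge keys are counted.
    """
    rows: dict[tuple[str, str, str], int] = {}
    for (h, r, t), triple in graph.edges.items():
        key = (graph.nodes[h].entity_type, r, graph.nodes[t].entity_type)
        rows[key] = rows.get(key, 0) + (triple.count if weighted else 1)
    df = pd.DataFrame(
        [(h, r, t, c) for (h, r, t), c in rows.items()],
        columns=["head_type", "relation", "tail_type", "count"],
    )
    return df.sort_values(
        ["count", "head_type", "relation", "tail_type"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)


def export_graph(graph: KnowledgeGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write node and edge TSVs that re-read to an identical graph."""
    write_node_types(nodes_path, {n: rec.entity_type for n, rec in graph.nodes.items()})
    write_triples(edges_path, [graph.edges[k] for k in sorted(graph.edges)])


def read_graph(nodes_path: str | Path, edges_path: str | Path, permissive: bool = True) -> KnowledgeGraph:
    return build_graph(read_triples(edges_path, permissive=permissive), read_node_types(nodes_path))


#: Mapping of Hetionet-style node kinds onto the 7 closed entity types.
HETIONET_KIND_MAP: dict[str, str] = {
    "compound": "compound",
    "disease": "phenotype",
    "symptom": "phenotype",
    "side effect": "phenotype",
    "anatomy": "phenotype",
    "gene": "gene",
    "pathway": "biological_process",
    "biological process": "biological_process",
    "molecular function": "molecular_function",
    "cellular component": "biological_process",
    "pharmacologic class": "compound",
}


def read_hetionet_json(path: str | Path, default_type: str = "phenotype") -> KnowledgeGraph:
    """Import a hetionet-v1.0-style JSON ({"nodes": [...], "edges": [...]}).

    Nodes carry (identifier, name, kind); edges reference endpoints by
    [kind, identifier] pairs and carry a relation kind plus direction.
    Relations are admitted permissively (Hetionet kinds such as "treats"
    or "binds" are outside the 28-predicate vocabulary); node kinds map
    onto the 7 entity types via HETIONET_KIND_MAP.
    """
    with open(path) as fh:
        payload = json.load(fh)
    graph = KnowledgeGraph()
    by_ref: dict[tuple[str, str], str] = {}
    for node in payload["nodes"]:
        kind = str(node["kind"]).lower()
        etype = HETIONET_KIND_MAP.get(kind, default_type)
        node_id = normalize_name(str(node["name"]))
        by_ref[(str(node["kind"]), str(node["identifier"]))] = node_id
        graph.add_node(EntityRecord(node_id, etype))
    for edge in payload["edges"]:
        src = edge["source_id"]
        tgt = edge["target_id"]
        head = by_ref[(str(src[0]), str(src[1]))]
        tail = by_ref[(str(tgt[0]), str(tgt[1]))]
        if head == tail:
            logger.warning("dropping self-loop on %r during hetionet import", head)
            continue
        relation = normalize_relation(str(edge["kind"]))
        graph.add_triple(Triple(head, relation, tail))
    return graph
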