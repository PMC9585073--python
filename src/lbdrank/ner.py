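"""Dictionary-based entity extraction and relation-input preparation.

Sentences are tagged by case-insensitive longest-match lookup against one
or more term dictionaries; sentences with at least two distinct entities
yield one relation input per unordered entity pair, with the pair's
mentions masked by their entity-type tokens ("@COMPOUND$ treats
@PHENOTYPE$").  Relation classification itself is injectable: any callable
mapping a RelationInput to (relation label, confidence) works, and a
deterministic type-pair fallback ships for testing, since the interesting
behaviour of the pipeline lies downstream of the classifier.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .kg_core import (
    ENTITY_TYPES,
    ValidationError,
    Triple,
    normalize_name,
    validate_relation,
)

logger = logging.getLogger(__name__)


@dataclass
class Dictionary:
    """Normalized term -> (canonical node_id, entity_type), with a priority
    used to break ties when multiple dictionaries match the same span."""

    entries: dict[str, tuple[str, str]]
    priority: int = 0


@dataclass(frozen=True)
class EntityMention:
    sentence_id: str
    start: int
    end: int  # 0-based half-open character offsets
    node_id: str
    entity_type: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"empty span [{self.start}, {self.end})")


@dataclass(frozen=True)
class RelationInput:
    sentence_id: str
    masked_text: str
    head: str
    head_type: str
    tail: str
    tail_type: str


def compile_dictionary(
    entries: Sequence[tuple[str, str, str]], priority: int = 0
) -> Dictionary:
    """Build a Dictionary from (term, canonical_id, entity_type) rows.

    Terms are normalized like node names; on duplicate normalized terms the
    first entry wins and a warning is logged.
    """
    if not entries:
        raise ValidationError("empty dictionary entry list")
    compiled: dict[str, tuple[str, str]] = {}
    for term, canonical_id, entity_type in entries:
        if entity_type not in ENTITY_TYPES:
            raise ValidationError(
                f"entity_type {entity_type!r} not in {sorted(ENTITY_TYPES)}"
            )
        key = normalize_name(term)
        if key in compiled:
            logger.warning("duplicate dictionary term %r; first entry wins", key)
            continue
        compiled[key] = (normalize_name(canonical_id), entity_type)
    return Dictionary(compiled, priority)


def read_dictionary_tsv(path: str | Path, priority: int = 0) -> Dictionary:
    """Read a dictionary TSV: term, canonical_id, entity_type."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValidationError(f"{path}: expected 3 columns, got {len(cols)}")
            rows.append((cols[0], cols[1], cols[2].strip().lower()))
    return compile_dictionary(rows, priority)


def _term_pattern(normalized_term: str) -> re.Pattern[str]:
    # underscores in the normalized key match spaces or hyphens in text
    parts = [re.escape(p) for p in normalized_term.split("_")]
    body = r"[\s\-]+".join(parts)
    return re.compile(rf"(?<![0-9A-Za-z]){body}(?![0-9A-Za-z])", re.IGNORECASE)


def extract_entities(
    sentence: str, dictionaries: Sequence[Dictionary], sentence_id: str = "s0"
) -> list[EntityMention]:
    """Case-insensitive longest-match tagging of one sentence.

    Overlapping candidates are resolved by longer span, then higher
    dictionary priority, then leftmost start; the result is non-overlapping
    and ordered by start offset.
    """
    if not sentence:
        raise ValidationError("empty sentence")
    candidates: list[tuple[int, int, int, str, str]] = []
    for d in dictionaries:
        for term, (node_id, entity_type) in d.entries.items():
            for m in _term_pattern(term).finditer(sentence):
                candidates.append((m.start(), m.end(), d.priority, node_id, entity_type))
    # longer span first, then higher priority, then leftmost
    candidates.sort(key=lambda c: (-(c[1] - c[0]), -c[2], c[0], c[3]))
    taken: list[tuple[int, int]] = []
    mentions: list[EntityMention] = []
    for start, end, _prio, node_id, entity_type in candidates:
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        mentions.append(EntityMention(sentence_id, start, end, node_id, entity_type))
    mentions.sort(key=lambda m: m.start)
    return mentions


def _type_token(entity_type: str) -> str:
    return f"@{entity_type.upper()}$"


def prepare_relation_inputs(
    sentences: Sequence[tuple[str, str]],
    mentions: Sequence[EntityMention],
) -> list[RelationInput]:
    """Pair up entities per sentence and mask their mentions with type tokens.

    Sentences with fewer than two distinct node_ids are skipped.  For u >= 2
    distinct entities, C(u, 2) inputs are produced — one per unordered pair —
    with head/tail ordered by first mention position.
    """
    by_sentence: dict[str, list[EntityMention]] = {}
    for m in mentions:
        by_sentence.setdefault(m.sentence_id, []).append(m)
    out: list[RelationInput] = []
    for sentence_id, text in sentences:
        sent_mentions = sorted(by_sentence.get(sentence_id, []), key=lambda m: m.start)
        for m in sent_mentions:
            if m.end > len(text):
                raise ValidationError(
                    f"mention span [{m.start}, {m.end}) outside sentence {sentence_id!r}"
                )
        first_pos: dict[str, int] = {}
        types: dict[str, str] = {}
        for m in sent_mentions:
            first_pos.setdefault(m.node_id, m.start)
            types.setdefault(m.node_id, m.entity_type)
        unique = sorted(first_pos, key=first_pos.__getitem__)
        if len(unique) < 2:
            continue
        for head, tail in itertools.combinations(unique, 2):
            pair = {head, tail}
            pieces: list[str] = []
            cursor = 0
            for m in sent_mentions:
                if m.node_id not in pair:
                    continue
                pieces.append(text[cursor : m.start])
                pieces.append(_type_token(m.entity_type))
                cursor = m.end
            pieces.append(text[cursor:])
            out.append(
                RelationInput(
                    sentence_id,
                    "".join(pieces),
                    head,
                    types[head],
                    tail,
                    types[tail],
                )
            )
    return out


#: A relation predictor maps a RelationInput to (relation label, confidence).
RelationPredictor = Callable[[RelationInput], tuple[str, float]]


def type_pair_predictor(
    table: Mapping[tuple[str, str], str] | None = None,
    default: str = "coexists_with",
    confidence: float = 1.0,
) -> RelationPredictor:
    """Deterministic fallback predictor keyed on the pair's entity types.

    Stands in for a trained sentence-level relation classifier in tests and
    examples; real deployments inject their own callable.
    """
    table = dict(table or {})

    def predict(ri: RelationInput) -> tuple[str, float]:
        return table.get((ri.head_type, ri.tail_type), default), confidence

    return predict


def assemble_triples(
    relation_inputs: Sequence[RelationInput],
    predictor: RelationPredictor,
    threshold: float = 0.0,
    doc_ids: Mapping[str, str] | None = None,
) -> list[Triple]:
    """Run the predictor over relation inputs and merge duplicate triples.

    Predictions below ``threshold`` are dropped; head/tail order follows
    mention order in the sentence.  Duplicate (head, relation, tail) keys
    across sentences merge with count increments and accumulated provenance.
    """
    merged: dict[tuple[str, str, str], Triple] = {}
    for ri in relation_inputs:
        label, confidence = predictor(ri)
        label = validate_relation(label)
        if confidence < threshold:
            continue
        prov: tuple[str, ...] = ()
        if doc_ids and ri.sentence_id in doc_ids:
            prov = (doc_ids[ri.sentence_id],)
        triple = Triple(ri.head, label, ri.tail, 1, prov)
        existing = merged.get(triple.key)
        if existing is None:
            merged[triple.key] = triple
        else:
            existing.count += 1
            existing.provenance = existing.provenance + tuple(
                p for p in prov if p not in existing.provenance
            )
    return [merged[k] for k in sorted(merged)]


def write_mentions_tsv(path: str | Path, mentions: Iterable[EntityMention]) -> None:
    with open(path, "w") as fh:
        fh.write("# sentence_id\tstart\tend\tnode_id\tentity_type\n")
        for m in mentions:
            fh.write(f"{m.sentence_id}\t{m.start}\t{m.end}\t{m.node_id}\t{m.entity_type}\n")
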