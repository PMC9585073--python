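"""Simple-path enumeration, scoring, ranking, and top-percentile selection.

Traversal is undirected — a closed-discovery path may chain assertions
whose natural subject->object directions alternate (compound binds gene,
gene associates disease) — but each traversed edge keeps its stored
orientation and relation label.  A path's depth is its exact edge count
(1-4); its score is the arithmetic mean of its per-edge triple scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path as FilePath
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kg_core import KnowledgeGraph, ValidationError

logger = logging.getLogger(__name__)

MAX_DEPTH = 4


class PathOverflowError(RuntimeError):
    """Raised when enumeration exceeds the configured hard cap."""


@dataclass(frozen=True)
class Path:
    """A simple path: node sequence plus oriented edge sequence.

    Each edge is (head, relation, tail, forward); ``forward`` records
    whether traversal followed the stored head->tail direction.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, str, bool], ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError(f"not a simple path: {self.nodes}")
        if len(self.edges) != len(self.nodes) - 1:
            raise ValidationError("edge sequence length must be node count - 1")
        for i, (h, r, t, forward) in enumerate(self.edges):
            expect = (self.nodes[i], self.nodes[i + 1]) if forward else (self.nodes[i + 1], self.nodes[i])
            if (h, t) != expect:
                raise ValidationError(f"edge {i} does not join consecutive nodes")

    @property
    def depth(self) -> int:
        return len(self.edges)

    @property
    def relations(self) -> tuple[str, ...]:
        return tuple(r for (_, r, _, _) in self.edges)

    def render(self) -> str:
        """Display form: "a—[rel]—b—[rel]—c" (em-dash and bracket style)."""
        parts = [self.nodes[0]]
        for (_, r, _, _), node in zip(self.edges, self.nodes[1:]):
            parts.append(f"[{r}]")
            parts.append(node)
        return "—".join(parts)


def enumerate_paths(
    graph: KnowledgeGraph,
    sources: Iterable[str],
    target: str,
    depth: int,
    cap: int | None = None,
) -> list[Path]:
    """All simple paths of exactly ``depth`` edges from any source to the target.

    Edges are traversed in either direction; parallel edges with distinct
    relations yield distinct paths.  The output is ordered lexicographically
    by node sequence then relation sequence.  ``cap`` bounds the number of
    emitted paths, raising PathOverflowError rather than truncating.
    """
    if depth not in range(1, MAX_DEPTH + 1):
        raise ValidationError(f"depth must be in 1..{MAX_DEPTH}, got {depth}")
    if target not in graph.nodes:
        raise ValidationError(f"unknown target node {target!r}")
    known_sources = []
    for s in sorted(set(sources)):
        if s == target:
            raise ValidationError(f"source equals target: {s!r}")
        if s not in graph.nodes:
            logger.warning("skipping unknown source %r", s)
            continue
        known_sources.append(s)

    out: list[Path] = []

    def dfs(node: str, visited: list[str], edges: list[tuple[str, str, str, bool]]) -> None:
        if len(edges) == depth:
            if node == target:
                out.append(Path(tuple(visited), tuple(edges)))
                if cap is not None and len(out) > cap:
                    raise PathOverflowError(f"more than {cap} paths emitted")
            return
        for other, h, r, t, forward in graph.neighbors(node):
            if other in visited:
                continue
            # target may only appear as the terminal node
            if other == target and len(edges) + 1 < depth:
                continue
            visited.append(other)
            edges.append((h, r, t, forward))
            dfs(other, visited, edges)
            visited.pop()
            edges.pop()

    for s in known_sources:
        dfs(s, [s], [])
    out.sort(key=lambda p: (p.nodes, p.relations))
    return out


@dataclass(frozen=True)
class ScoredPath:
    path: Path
    thetas: tuple[float, ...]
    path_score: float

    def __post_init__(self) -> None:
        mean = sum(self.thetas) / len(self.thetas)
        if abs(self.path_score - mean) > 1e-12:
            raise ValidationError("path_score must equal the mean of its thetas")


@dataclass
class Ranking:
    """Paths in non-increasing score order with a deterministic tie-break
    (lexicographic node sequence, then relation sequence)."""

    entries: list[ScoredPath]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def identifiers(self) -> list[str]:
        return [sp.path.render() for sp in self.entries]


def score_and_rank(
    paths: Sequence[Path], thetas: Mapping[tuple[str, str, str], float]
) -> Ranking:
    """Score each path as the mean of its edge thetas and sort descending."""
    scored: list[ScoredPath] = []
    for p in paths:
        vals = []
        for (h, r, t, _) in p.edges:
            if (h, r, t) not in thetas:
                raise ValidationError(f"no triple score for edge ({h}, {r}, {t})")
            vals.append(thetas[(h, r, t)])
        scored.append(ScoredPath(p, tuple(vals), sum(vals) / len(vals)))
    scored.sort(key=lambda sp: (-sp.path_score, sp.path.nodes, sp.path.relations))
    return Ranking(scored)


def top_percentile_count(n: int, pct: float) -> int:
    """ceil(pct/100 * n) — the size of a top-percentile selection."""
    if not 0 < pct < 100:
        raise ValidationError(f"pct must be in (0, 100), got {pct}")
    return math.ceil(pct / 100.0 * n)


def select_top_percentile(ranking: Ranking, pct: float = 5.0) -> list[ScoredPath]:
    """The first ceil(pct/100 * N) entries of the ranking."""
    if len(ranking) == 0:
        return []
    return ranking.entries[: top_percentile_count(len(ranking), pct)]


def path_count_matrix(
    graph: KnowledgeGraph,
    sources: Sequence[str],
    targets: Sequence[str],
    depths: Sequence[int],
    cap: int | None = None,
) -> pd.DataFrame:
    """Count matrix: rows = sources, columns = (target, depth), plus totals.

    Cell (s, t, d) is the number of depth-d simple paths from s to t.  A
    "Total" row and column are appended; the bottom-right cell is the grand
    total over all source/target/depth cells.
    """
    columns = pd.MultiIndex.from_product([list(targets), list(depths)], names=["target", "depth"])
    df = pd.DataFrame(0, index=list(sources), columns=columns, dtype=int)
    for t in targets:
        for d in depths:
            for s in sources:
                df.loc[s, (t, d)] = len(enumerate_paths(graph, [s], t, d, cap=cap))
    df.loc["Total"] = df.sum(axis=0)
    df[("Total", "")] = df.sum(axis=1)
    return df


def grand_total(matrix: pd.DataFrame) -> int:
    """Sum of all per-(source, target, depth) cells of a count matrix.

    Accepts either a full matrix from path_count_matrix (totals excluded
    from the sum) or any plain cell table.
    """
    df = matrix
    if "Total" in df.index:
        df = df.drop(index="Total")
    if isinstance(df.columns, pd.MultiIndex) and ("Total", "") in df.columns:
        df = df.drop(columns=[("Total", "")])
    return int(df.to_numpy().sum())


def write_ranked_paths(path: str | FilePath, ranking: Ranking) -> None:
    """Ranked-paths TSV: rank, rendered path, display score, machine score."""
    with open(path, "w") as fh:
        fh.write("# rank\tpath\tpath_score\tpath_score_full\n")
        for rank, sp in enumerate(ranking, start=1):
            fh.write(f"{rank}\t{sp.path.render()}\t{sp.path_score:.3f}\t{sp.path_score:.9f}\n")


def write_count_matrix(path: str | FilePath, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path)
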