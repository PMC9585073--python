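"""Rank-biased overlap (RBO) between two rankings of the same path set.

RBO weights agreement at the top of the lists more heavily than at the
bottom, governed by a persistence parameter p in (0, 1): with A_d the
proportional overlap of the two depth-d prefixes, the extrapolated RBO
over conjoint lists of length l is

    RBO_ext = (1 - p) * sum_{d=1}^{l} A_d p^(d-1)  +  A_l * p^l .

Identical lists give 1, fully disjoint lists give 0, and the measure is
symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .kg_core import ValidationError


@dataclass(frozen=True)
class RankedList:
    """An ordered list of unique path identifiers with a source label."""

    identifiers: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.identifiers:
            raise ValidationError(f"empty ranked list (source={self.source!r})")
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValidationError(f"duplicate identifiers in ranked list (source={self.source!r})")

    def __len__(self) -> int:
        return len(self.identifiers)


def rbo_similarity(
    list_a: RankedList | Sequence[str],
    list_b: RankedList | Sequence[str],
    p: float = 0.9,
) -> float:
    """Extrapolated RBO of two equal-length conjoint rankings."""
    a = list_a if isinstance(list_a, RankedList) else RankedList(tuple(list_a))
    b = list_b if isinstance(list_b, RankedList) else RankedList(tuple(list_b))
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie in (0, 1), got {p}")
    if len(a) != len(b):
        raise ValidationError(f"list lengths differ: {len(a)} vs {len(b)}")
    length = len(a)
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    overlap = 0
    weighted = 0.0
    agreement = 0.0
    pw = 1.0   # p^(d-1)
    for d in range(1, length + 1):
        x, y = a.identifiers[d - 1], b.identifiers[d - 1]
        if x == y:
            overlap += 1
        else:
            overlap += (x in seen_b) + (y in seen_a)
        seen_a.add(x)
        seen_b.add(y)
        agreement = overlap / d
        weighted += agreement * pw
        pw *= p
    return (1.0 - p) * weighted + agreement * pw   # pw is now p^length


@dataclass
class AgreementReport:
    rows: pd.DataFrame          # source, depth, n_paths, similarity_pct
    mean_pct: float
    min_pct: float
    max_pct: float


def agreement_report(
    pairs: Sequence[tuple[str, RankedList | Sequence[str], RankedList | Sequence[str], int]],
    p: float = 0.9,
) -> AgreementReport:
    """Per-source RBO similarity as percentages, sorted ascending.

    Each pair is (source, produced ranking, reference ranking, depth);
    the aggregate carries the arithmetic mean, min and max of the rows.
    """
    if not pairs:
        raise ValidationError("at least one ranking pair is required")
    records = []
    for source, la, lb, depth in pairs:
        sim = rbo_similarity(la, lb, p) * 100.0
        n = len(la if isinstance(la, RankedList) else tuple(la))
        records.append({"source": source, "depth": depth, "n_paths": n, "similarity_pct": sim})
    df = pd.DataFrame(records).sort_values(
        ["similarity_pct", "source"], ascending=[True, True]
    ).reset_index(drop=True)
    sims = df["similarity_pct"]
    return AgreementReport(df, float(sims.mean()), float(sims.min()), float(sims.max()))


def write_agreement_report(path: str | Path, report: AgreementReport) -> None:
    df = report.rows.copy()
    df["similarity_pct"] = df["similarity_pct"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False)
    with open(path, "a") as fh:
        fh.write(f"# mean={report.mean_pct:.2f} min={report.min_pct:.2f} max={report.max_pct:.2f}\n")


def read_reference_ranking(path: str | Path) -> dict[str, RankedList]:
    """Read a reference-ranking TSV of (source, rank, path identifier)."""
    by_source: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            source, rank, ident = line.split("\t")
            by_source.setdefault(source, []).append((int(rank), ident))
    return {
        source: RankedList(tuple(ident for _, ident in sorted(items)), source)
        for source, items in by_source.items()
    }
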