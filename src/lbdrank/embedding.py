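"""ComplEx knowledge-graph embeddings.

Entities and relations are complex-valued vectors; a triple (h, r, t) is
scored by the real part of the trilinear product

    score(h, r, t) = Re( sum_i  w_r[i] * e_h[i] * conj(e_t[i]) )

which is asymmetric in h and t whenever Im(w_r) != 0, letting one model
learn both symmetric and directed relations.  Training is by negative
sampling: each observed triple is contrasted against corruptions with a
uniformly resampled head or tail, under a logistic loss with L2
regularization, optimized by Adagrad-style per-parameter steps.  All
randomness flows from the config seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kg_core import KnowledgeGraph, ValidationError


@dataclass
class ComplExConfig:
    k: int = 50                 # embedding dimension (complex components)
    epochs: int = 100
    learning_rate: float = 0.05
    negatives: int = 20         # corruptions per observed triple
    regularization: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.epochs + 1, self.negatives) < 1 or self.learning_rate <= 0:
            raise ValidationError(f"non-positive training config: {self}")


@dataclass
class EmbeddingTable:
    """Complex entity/relation vectors plus the config that produced them."""

    entity_embeddings: dict[str, np.ndarray]
    relation_embeddings: dict[str, np.ndarray]
    k: int
    config: ComplExConfig | None = None
    loss_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, vec in {**self.entity_embeddings, **self.relation_embeddings}.items():
            if vec.shape != (self.k,):
                raise ValidationError(f"vector {name!r} has shape {vec.shape}, expected ({self.k},)")
            if not np.all(np.isfinite(vec.view(float))):
                raise ValidationError(f"non-finite entries in vector {name!r}")

    def entity(self, node_id: str) -> np.ndarray:
        try:
            return self.entity_embeddings[node_id]
        except KeyError:
            raise ValidationError(f"no embedding for entity {node_id!r}") from None

    def relation(self, label: str) -> np.ndarray:
        try:
            return self.relation_embeddings[label]
        except KeyError:
            raise ValidationError(f"no embedding for relation {label!r}") from None


def complex_score(e_h: np.ndarray, w_r: np.ndarray, e_t: np.ndarray) -> float:
    """Re(sum_i w_r[i] * e_h[i] * conj(e_t[i]))."""
    e_h, w_r, e_t = (np.asarray(v, dtype=complex) for v in (e_h, w_r, e_t))
    if not (e_h.shape == w_r.shape == e_t.shape):
        raise ValidationError(
            f"dimension mismatch: {e_h.shape}, {w_r.shape}, {e_t.shape}"
        )
    return float(np.real(np.sum(w_r * e_h * np.conj(e_t))))


def _batch_scores(hr, hi, rr, ri, tr, ti):
    return np.sum(hr * rr * tr + hi * rr * ti + hr * ri * ti - hi * ri * tr, axis=1)


def train_complex(graph: KnowledgeGraph, config: ComplExConfig | None = None) -> EmbeddingTable:
    """Fit ComplEx embeddings to the graph's directed edge keys.

    Edges are trained as stored (head -> tail); parallel edges with
    different relations are independent training triples.  Per-epoch mean
    loss is recorded in the returned table's ``loss_log``.
    """
    config = config or ComplExConfig()
    if graph.num_edges == 0:
        raise ValidationError("cannot train embeddings on an empty graph")
    rng = np.random.default_rng(config.seed)

    entities = sorted(graph.nodes)
    relations = graph.relation_labels()
    ent_ix = {e: i for i, e in enumerate(entities)}
    rel_ix = {r: i for i, r in enumerate(relations)}
    n_ent, n_rel, k = len(entities), len(relations), config.k

    # Xavier-style init on both real and imaginary parts
    scale = 1.0 / np.sqrt(k)
    E = rng.normal(0.0, scale, size=(n_ent, 2 * k))   # [:, :k]=Re, [:, k:]=Im
    R = rng.normal(0.0, scale, size=(n_rel, 2 * k))
    gE = np.full_like(E, 1e-8)   # Adagrad accumulators
    gR = np.full_like(R, 1e-8)

    keys = sorted(graph.edges)
    H = np.array([ent_ix[h] for h, _, _ in keys])
    Rl = np.array([rel_ix[r] for _, r, _ in keys])
    T = np.array([ent_ix[t] for _, _, t in keys])
    m = len(keys)
    neg = config.negatives
    reg, lr = config.regularization, config.learning_rate

    loss_log: list[float] = []
    for _ in range(config.epochs):
        corrupt_ent = rng.integers(0, n_ent, size=m * neg)
        corrupt_head = rng.random(m * neg) < 0.5
        Hb = np.concatenate([H, np.where(corrupt_head, corrupt_ent, np.repeat(H, neg))])
        Tb = np.concatenate([T, np.where(corrupt_head, np.repeat(T, neg), corrupt_ent)])
        Rb = np.concatenate([Rl, np.repeat(Rl, neg)])
        y = np.concatenate([np.ones(m), -np.ones(m * neg)])

        hr, hi = E[Hb, :k], E[Hb, k:]
        rr, ri = R[Rb, :k], R[Rb, k:]
        tr, ti = E[Tb, :k], E[Tb, k:]
        s = _batch_scores(hr, hi, rr, ri, tr, ti)
        # logistic loss: softplus(-y*s)
        z = -y * s
        loss = float(np.mean(np.logaddexp(0.0, z)))
        loss_log.append(loss)
        dL_ds = (-y) * (1.0 / (1.0 + np.exp(-z)))    # -y * sigmoid(-y*s)
        w = (dL_ds / len(y))[:, None]
        wreg = reg / len(y)   # L2 applied per sample occurrence, matching the mean loss

        d_hr = w * (rr * tr + ri * ti) + wreg * hr
        d_hi = w * (rr * ti - ri * tr) + wreg * hi
        d_rr = w * (hr * tr + hi * ti) + wreg * rr
        d_ri = w * (hr * ti - hi * tr) + wreg * ri
        d_tr = w * (hr * rr - hi * ri) + wreg * tr
        d_ti = w * (hi * rr + hr * ri) + wreg * ti

        gradE = np.zeros_like(E)
        gradR = np.zeros_like(R)
        np.add.at(gradE, Hb, np.concatenate([d_hr, d_hi], axis=1))
        np.add.at(gradE, Tb, np.concatenate([d_tr, d_ti], axis=1))
        np.add.at(gradR, Rb, np.concatenate([d_rr, d_ri], axis=1))

        gE += gradE**2
        gR += gradR**2
        E -= lr * gradE / np.sqrt(gE)
        R -= lr * gradR / np.sqrt(gR)

    ent_vecs = {e: (E[i, :k] + 1j * E[i, k:]).copy() for e, i in ent_ix.items()}
    rel_vecs = {r: (R[i, :k] + 1j * R[i, k:]).copy() for r, i in rel_ix.items()}
    return EmbeddingTable(ent_vecs, rel_vecs, k, config, loss_log)


def score_graph_edges(table: EmbeddingTable, graph: KnowledgeGraph) -> dict[tuple[str, str, str], float]:
    """complex_score for every edge key of the graph."""
    return {
        (h, r, t): complex_score(table.entity(h), table.relation(r), table.entity(t))
        for (h, r, t) in sorted(graph.edges)
    }


# ---------------------------------------------------------------------------
# Persistence: TSV with Re and Im component columns, exact to written precision
# ---------------------------------------------------------------------------


def save_embeddings(path: str | Path, table: EmbeddingTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={table.k}\n")
        for kind, vectors in (("entity", table.entity_embeddings), ("relation", table.relation_embeddings)):
            for name in sorted(vectors):
                vec = vectors[name]
                comps = "\t".join(repr(float(x)) for x in np.concatenate([vec.real, vec.imag]))
                fh.write(f"{kind}\t{name}\t{comps}\n")


def load_embeddings(path: str | Path) -> EmbeddingTable:
    entity: dict[str, np.ndarray] = {}
    relation: dict[str, np.ndarray] = {}
    k = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if "k=" in line:
                    k = int(line.split("k=")[1])
                continue
            if not line.strip():
                continue
            kind, name, *comps = line.split("\t")
            vals = np.array([float(c) for c in comps])
            half = len(vals) // 2
            vec = vals[:half] + 1j * vals[half:]
            (entity if kind == "entity" else relation)[name] = vec
            if k is None:
                k = half
    if k is None:
        raise ValidationError(f"no embeddings found in {path}")
    return EmbeddingTable(entity, relation, k)
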