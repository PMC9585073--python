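"""Autoencoder-derived triple scoring.

Each triple is represented by the concatenation of its head, relation and
tail embedding components,

    v = [Re(e_h), Im(e_h), Re(w_r), Im(w_r), Re(e_t), Im(e_t)],   n = 6k,

and the full set of edge triple vectors trains a seven-layer
encoder-decoder (three encoder layers, a bottleneck middle, three decoder
layers; sizes n -> n/2 -> n/4 -> n/8 -> n/4 -> n/2 -> n, ReLU hidden,
linear output) under mean-squared reconstruction error.  The scoring
weight vector h is read off the final decoder layer as the mean over its
hidden units of the outgoing weights — one value per reconstructed
coordinate, so h shares v's dimension — and the triple score is

    theta = sigmoid(v . h)  in (0, 1).

The sigmoid is the minimal monotone map from the unbounded dot product to
a probability; everything upstream of it is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embedding import EmbeddingTable
from .kg_core import KnowledgeGraph, Triple, ValidationError


@dataclass(frozen=True)
class TripleVector:
    key: tuple[str, str, str]
    v: np.ndarray

    def __post_init__(self) -> None:
        if self.v.ndim != 1 or self.v.size % 6 != 0:
            raise ValidationError(f"triple vector must be 1-D with size 6k, got {self.v.shape}")
        if not np.all(np.isfinite(self.v)):
            raise ValidationError(f"non-finite triple vector for {self.key}")


def build_triple_vector(embeddings: EmbeddingTable, triple: Triple) -> TripleVector:
    """Concatenate [Re(e_h), Im(e_h), Re(w_r), Im(w_r), Re(e_t), Im(e_t)]."""
    e_h = embeddings.entity(triple.head)
    w_r = embeddings.relation(triple.relation)
    e_t = embeddings.entity(triple.tail)
    v = np.concatenate([e_h.real, e_h.imag, w_r.real, w_r.imag, e_t.real, e_t.imag])
    return TripleVector(triple.key, v)


def build_triple_vectors(embeddings: EmbeddingTable, graph: KnowledgeGraph) -> list[TripleVector]:
    return [build_triple_vector(embeddings, graph.edges[k]) for k in sorted(graph.edges)]


@dataclass
class AutoencoderConfig:
    epochs: int = 300
    learning_rate: float = 1e-2   # Adam step size
    batch_size: int = 64
    seed: int = 0
    reduction: str = "mean"       # how the scoring vector is reduced from the last layer

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValidationError(f"invalid autoencoder config: {self}")
        if self.reduction not in ("mean", "sum"):
            raise ValidationError(f"reduction must be 'mean' or 'sum', got {self.reduction!r}")


def _layer_sizes(n: int) -> list[int]:
    n2, n4, n8 = math.ceil(n / 2), math.ceil(n / 4), math.ceil(n / 8)
    return [n, n2, n4, n8, n4, n2, n]


@dataclass
class AutoencoderModel:
    """Seven-layer encoder-decoder: weights[i] maps sizes[i] -> sizes[i+1]."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    sizes: list[int]
    config: AutoencoderConfig
    loss_log: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.sizes[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        A = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            A = A @ W + b
            if i < last:
                A = np.maximum(A, 0.0)   # ReLU on hidden layers, linear output
        return A

    def reconstruction_mse(self, X: np.ndarray) -> float:
        return float(np.mean((self.forward(X) - X) ** 2))


def train_autoencoder(
    vectors: Sequence[TripleVector] | np.ndarray,
    config: AutoencoderConfig | None = None,
) -> AutoencoderModel:
    """Train the bottleneck autoencoder on triple vectors with MSE loss.

    Adam optimization over mini-batches; per-epoch mean loss is recorded.
    Deterministic given the config seed.
    """
    config = config or AutoencoderConfig()
    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=float)
    else:
        if not vectors:
            raise ValidationError("no triple vectors to train on")
        dims = {tv.v.size for tv in vectors}
        if len(dims) != 1:
            raise ValidationError(f"inconsistent triple-vector dimensions: {sorted(dims)}")
        X = np.stack([tv.v for tv in vectors])
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError(f"expected a (m, n) matrix of vectors, got {X.shape}")

    n = X.shape[1]
    sizes = _layer_sizes(n)
    rng = np.random.default_rng(config.seed)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(fan_out) for fan_out in sizes[1:]]
    model = AutoencoderModel(weights, biases, sizes, config)

    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    m_samples = X.shape[0]

    for _ in range(config.epochs):
        order = rng.permutation(m_samples)
        epoch_losses = []
        for start in range(0, m_samples, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            # forward pass, caching activations
            acts = [batch]
            A = batch
            last = len(weights) - 1
            for i, (W, b) in enumerate(zip(weights, biases)):
                Z = A @ W + b
                A = np.maximum(Z, 0.0) if i < last else Z
                acts.append(A)
            diff = acts[-1] - batch
            epoch_losses.append(float(np.mean(diff**2)))
            # backward pass (MSE)
            delta = 2.0 * diff / diff.size
            step += 1
            for i in range(last, -1, -1):
                gW = acts[i].T @ delta
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ weights[i].T) * (acts[i] > 0)
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW**2
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb**2
                c1, c2 = 1 - beta1**step, 1 - beta2**step
                weights[i] -= config.learning_rate * (mW[i] / c1) / (np.sqrt(vW[i] / c2) + eps)
                biases[i] -= config.learning_rate * (mb[i] / c1) / (np.sqrt(vb[i] / c2) + eps)
        model.loss_log.append(float(np.mean(epoch_losses)))
    return model


@dataclass(frozen=True)
class ScoringWeights:
    h: np.ndarray
    source: str

    def __post_init__(self) -> None:
        if self.h.ndim != 1 or not np.all(np.isfinite(self.h)):
            raise ValidationError("scoring weights must be a finite 1-D vector")


def extract_scoring_weights(model: AutoencoderModel, reduction: str | None = None) -> ScoringWeights:
    """Reduce the final decoder layer's weight matrix to one value per
    output coordinate (mean over hidden units by default, sum optionally)."""
    if not model.weights:
        raise ValidationError("model has no trained layers")
    reduction = reduction or model.config.reduction
    W_last = model.weights[-1]   # (hidden, n)
    if reduction == "mean":
        h = W_last.mean(axis=0)
    elif reduction == "sum":
        h = W_last.sum(axis=0)
    else:
        raise ValidationError(f"unknown reduction {reduction!r}")
    return ScoringWeights(h, source=f"decoder_layer_{len(model.weights)}:{reduction}")


@dataclass(frozen=True)
class ScoredTriple:
    key: tuple[str, str, str]
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValidationError(f"theta must lie in (0, 1), got {self.theta}")


def score_triple(v: TripleVector, h: ScoringWeights) -> ScoredTriple:
    """theta = sigmoid(v . h)."""
    if v.v.shape != h.h.shape:
        raise ValidationError(f"dimension mismatch: v {v.v.shape} vs h {h.h.shape}")
    from scipy.special import expit

    return ScoredTriple(v.key, float(expit(float(v.v @ h.h))))


def score_triples(
    vectors: Sequence[TripleVector], h: ScoringWeights
) -> dict[tuple[str, str, str], float]:
    """theta lookup table for a batch of triple vectors."""
    return {tv.key: score_triple(tv, h).theta for tv in vectors}


def write_scored_triples(path: str | Path, thetas: Mapping[tuple[str, str, str], float]) -> None:
    with open(path, "w") as fh:
        fh.write("# head\trelation\ttail\ttheta\n")
        for (head, rel, tail) in sorted(thetas):
            fh.write(f"{head}\t{rel}\t{tail}\t{thetas[(head, rel, tail)]:.9f}\n")


def read_scored_triples(path: str | Path) -> dict[tuple[str, str, str], float]:
    thetas: dict[tuple[str, str, str], float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            head, rel, tail, theta = line.split("\t")
            thetas[(head, rel, tail)] = float(theta)
    return thetas


def save_model(path: str | Path, model: AutoencoderModel) -> None:
    """Checkpoint the autoencoder as a plain-text npz-free TSV bundle."""
    with open(path, "w") as fh:
        fh.write(f"# sizes={','.join(map(str, model.sizes))} reduction={model.config.reduction}\n")
        for i, (W, b) in enumerate(zip(model.weights, model.biases)):
            for row in W:
                fh.write(f"W{i}\t" + "\t".join(repr(float(x)) for x in row) + "\n")
            fh.write(f"b{i}\t" + "\t".join(repr(float(x)) for x in b) + "\n")


def load_model(path: str | Path) -> AutoencoderModel:
    sizes: list[int] = []
    reduction = "mean"
    w_rows: dict[int, list[list[float]]] = {}
    b_rows: dict[int, list[float]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("sizes="):
                        sizes = [int(x) for x in tok[len("sizes="):].split(",")]
                    elif tok.startswith("reduction="):
                        reduction = tok[len("reduction="):]
                continue
            if not line.strip():
                continue
            tag, *vals = line.split("\t")
            idx = int(tag[1:])
            if tag.startswith("W"):
                w_rows.setdefault(idx, []).append([float(v) for v in vals])
            else:
                b_rows[idx] = [float(v) for v in vals]
    weights = [np.array(w_rows[i]) for i in sorted(w_rows)]
    biases = [np.array(b_rows[i]) for i in sorted(b_rows)]
    return AutoencoderModel(weights, biases, sizes, AutoencoderConfig(reduction=reduction))
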