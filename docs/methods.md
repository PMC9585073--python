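# Methods

`lbdrank` implements a closed-discovery (Swanson ABC) path-ranking
workflow for drug-repurposing hypothesis generation over a biomedical
knowledge graph.  Given a set of source compounds A and a target disease
C, the tool enumerates simple paths A—B₁—…—C through intermediate
concepts, scores each path from learned graph embeddings, and surfaces
the top few percent for expert review.  This note records the model, the
choices that were genuinely open, and what the synthetic benchmarks do
and do not show.

## Knowledge graph

Nodes are normalized concept names (lowercase; spaces and hyphens become
underscores; commas are kept, so "1,3-di-O-caffeoylquinic acid" becomes
`1,3_di_o_caffeoylquinic_acid`) typed over a closed 7-value set:
phenotype, compound, gene, protein, biological process, molecular
function, RNA.  Edges are (head, relation, tail) assertions from a closed
28-predicate SemMedDB-style vocabulary ("treats", "coexists with",
"inhibits", …), each carrying the number of supporting sentence-level
extractions.  Re-ingesting a duplicate key increments that count rather
than adding a parallel edge, which makes graph construction independent
of input order.  Self-loops are dropped at ingest: simple-path semantics
can never use them.  A permissive mode admits out-of-vocabulary relation
labels so that external networks (Hetionet-style JSON exports, whose edge
kinds such as "binds" or "palliates" are not among the 28) can be
imported; Hetionet node kinds are folded onto the 7 types by a
configurable map (Disease → phenotype, Pathway → biological process, …).

Evidence counts are stored but not used as training or scoring weights by
default; nothing in the scoring model below consumes them, and a
count-weighted variant would change the learned embeddings in ways we
have no reference behaviour for.  The schema summary exposes both
distinct-key and evidence-weighted tallies.

## Entity and relation extraction front-end

The dictionary-based tagger is a deliberately simple stand-in for a full
biomedical NER engine: case-insensitive longest-match scanning against
term dictionaries, with overlaps resolved by longer span, then dictionary
priority, then leftmost position.  Sentences with fewer than two distinct
entities are skipped.  For u ≥ 2 distinct entities every unordered pair —
C(u,2) inputs — is passed to the relation predictor, with the pair's
mentions masked by type tokens (`@COMPOUND$ treats @PHENOTYPE$`).
Relation classification itself is an injectable callable returning
(label, confidence); a deterministic type-pair fallback ships for testing
because the package's contribution is downstream of the classifier.  No
sentence splitting, abbreviation expansion or coreference is attempted.

## ComplEx embeddings

Entities and relations are complex vectors of dimension k; a triple is
scored by Re(Σᵢ w_r[i]·e_h[i]·conj(e_t[i])).  The imaginary part of w_r
controls asymmetry: a relation observed in both directions is driven
toward a real vector (symmetric scores), while a one-directional relation
retains a large imaginary part and scores direction-dependently — both
behaviours are verified on constructed graphs in the test suite.

Training is negative-sampling logistic regression: each observed triple
(label +1) is contrasted with corruptions (label −1) whose head or tail
is resampled uniformly (coin flip), under softplus loss with per-sample
L2 regularization, optimized with Adagrad-style per-parameter steps.
Edges are trained as stored (directed) even though path traversal is
undirected: direction is information ComplEx can use and traversal can
ignore.

Defaults (all config-exposed): k = 50, 100 epochs, learning rate 0.05,
20 negatives per positive, L2 3·10⁻³, Xavier-style seeded
initialization.  The negative count and regularization matter at desk
scale: with few negatives and weak L2 a desk-sized graph (hundreds of
nodes, ~10² parameters per node) is simply memorized — training loss
falls while held-out true triples score like corruptions.  Twenty
negatives per positive and the stronger shrinkage push the optimizer
toward the low-complexity solution that generalizes (held-out AUC ≈
0.93–0.95 on the synthetic benchmark below, vs ≈ 0.5–0.88 with 5
negatives and L2 10⁻³).  Training is fully vectorized and
bit-reproducible given the seed.

## Triple scoring

Each graph edge becomes a triple vector
v = [Re(e_h), Im(e_h), Re(w_r), Im(w_r), Re(e_t), Im(e_t)] of dimension
n = 6k.  All edge triple vectors train a seven-layer encoder–decoder
(three encoder layers, a bottleneck middle, three decoder layers) under
mean-squared reconstruction error with Adam (step 10⁻², batch 64, 300
epochs default).  The layer schedule is the symmetric bottleneck
n → ⌈n/2⌉ → ⌈n/4⌉ → ⌈n/8⌉ → ⌈n/4⌉ → ⌈n/2⌉ → n with ReLU hidden
activations and a linear output.

The scoring weight vector h is read off the final decoder layer: its
weight matrix maps ⌈n/2⌉ hidden units to the n output coordinates, and h
is the mean over hidden units of the outgoing weights — one value per
coordinate, so h shares v's dimension (a "sum" reduction is available as
config).  Averaging is the simplest dimension-correct reduction of "the
weights of the last decoder layer"; nothing deeper should be read into
it.  The triple score is θ = sigmoid(v·h): the raw dot product is
unbounded, and the sigmoid is the minimal monotone map onto (0,1) so that
θ can be treated as a probability.  θ is strictly increasing in v·h, and
negating h complements it.

## Path enumeration, ranking, selection

A path of depth d is a simple (no repeated node) chain of exactly d
edges; depths 1–4 are supported.  Traversal is undirected — biomedical
reasoning chains routinely oppose storage direction (compound binds gene,
gene associates disease) — but each traversed edge records its stored
orientation and label, and parallel edges with different relations yield
distinct paths.  Enumeration is exhaustive DFS with an optional hard cap
that raises rather than silently truncating; output order, and the
tie-break within equal scores, is lexicographic by node sequence then
relation sequence, making every downstream artifact deterministic.

A path's score is the arithmetic mean of its per-edge θ values; rankings
sort descending.  The top-percentile selection takes the first
⌈pct/100 · N⌉ entries.  The ceiling is chosen because it reproduces the
published worked-example count for one of the three disease targets
exactly (34,774 = ⌈5% · 695,472⌉); for the other two targets the
published counts exceed the ceiling rule by one (42,670 vs 42,669 and
59,575 vs 59,574), a discrepancy we document and do not attempt to
reconcile — the original rounding/tie policy is unknown.

## Rank-biased overlap

Ranking agreement against a reference (e.g. a Hetionet/DWPC-based
ranking) uses extrapolated RBO on equal-length conjoint lists: with A_d
the proportional overlap of depth-d prefixes,
RBO = (1−p)·Σ A_d p^(d−1) + A_ℓ p^ℓ.  Default persistence p = 0.9,
config-exposed.  For the published 14-path worked example the two
printed orderings give RBO ≈ 0.81 at p = 0.9; scanning p shows the curve
dipping to ≈ 0.73 near p ≈ 0.7 — close to, but never exactly, the
published 71.10%, whose p and RBO variant are unstated.  The figure is
therefore treated as a consistency reference, not a reproduction target.
Unequal-length lists are rejected rather than truncated.

## Synthetic data

The generator emulates the statistical skeleton of a literature-derived
network, not its content: nodes split over the 7 entity types (default
200 nodes, weighted toward phenotypes/compounds/genes the way extraction
outputs are), edges drawn from the 28 predicates, a Zipf-like degree
distribution (weight ∝ rank^−1.5), and a per-relation type signature —
each predicate links one head type to one tail type, the way "treats"
links compounds to phenotypes.  Held-out edges are drawn from the same
pattern but excluded from the graph, so a link predictor that learns
types and popularity separates them from uniform corruptions; planted
source→target paths at chosen depths give enumeration a known manifest.
The toy corpus generator plants dictionary terms with recorded offsets in
filler sentences for NER round-trips.

What passing these benchmarks does **not** show: real extraction noise
(mis-typed entities, wrong relations from the classifier), polysemy and
normalization collisions, the hub structure of real diseases, or
million-edge scale.  The synthetic AUC measures whether the training
pipeline can learn a planted regularity at desk size — a functional
check, not a claim about PubMed-scale performance.

## Problem sizes and numerics

Benchmarks run at desk scale by design: the planted graph uses 200 nodes
/ 1,000 edges with 500 held-out triples, the enumeration oracle uses 100
random graphs of ≤ 12 nodes at depths 1–4, and the RBO and complex-score
oracles use 1,000 random instances each (tolerances 10⁻¹² and 10⁻⁹).
Every stochastic component takes an explicit seed; two runs with the same
seeds produce byte-identical artifacts, which the acceptance script
verifies end to end.  Degenerate inputs fail loudly: empty graphs cannot
be embedded, empty ranked lists cannot be compared, unknown targets and
missing θ entries raise validation errors naming the offender.

## Known limitations

- The relation-classification stage is a contract, not a model; shipped
  predictors are deterministic stand-ins.
- h-extraction from the autoencoder is one defensible reading of "the
  last decoder layer's weights"; flattenings or other reductions would
  give different θ scales (the sigmoid keeps any of them in (0,1)).
- Path enumeration is exhaustive; beyond depth 4 or on dense graphs the
  count explodes and the cap exists to fail fast, not to sample.
- RBO is implemented only for equal-length conjoint lists, the regime
  the evaluation actually needs.
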