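# lbdrank

Literature-based-discovery path ranking over typed biomedical knowledge
graphs.

`lbdrank` is for computational drug-discovery researchers who mine the
literature with Swanson's closed-discovery ABC scheme: given known source
compounds **A** and a target disease **C**, find and prioritize the
intermediate concepts **B** that chain them together.  Starting from
(head, relation, tail) triples — e.g. the output of a biomedical NER +
relation-classification pipeline — the tool builds a typed multigraph,
learns ComplEx knowledge-graph embeddings, scores every triple with an
autoencoder-derived weight vector, enumerates simple paths from sources
to target, ranks them, and selects the top percentile as hypotheses.
Ranking agreement with a reference (e.g. a Hetionet/DWPC ranking) is
measured with rank-biased overlap.

## The model in brief

- **ComplEx scoring.** Entities and relations are complex vectors of
  dimension k; a triple scores
  `Re(Σᵢ w_r[i]·e_h[i]·conj(e_t[i]))`, trained by negative sampling so
  observed triples outrank corrupted ones.  The complex relation vector
  lets one model capture both symmetric ("coexists with") and directed
  ("causes") predicates.
- **Triple score θ.** Each edge's vector
  `v = [Re(e_h), Im(e_h), Re(w_r), Im(w_r), Re(e_t), Im(e_t)]` (n = 6k)
  feeds a seven-layer encoder–decoder trained with MSE reconstruction
  loss; the weight vector **h** is read off the last decoder layer, and
  `θ = sigmoid(v·h) ∈ (0,1)`.
- **Path score.** A depth-d path (exactly d edges, no repeated node,
  traversal ignores stored edge direction) scores the arithmetic mean of
  its d triple scores; rankings sort descending and the top
  `⌈pct/100·N⌉` paths are kept.
- **RBO.** Extrapolated rank-biased overlap with persistence p compares
  two orderings of the same path set, weighting the top of the lists
  most.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

The package ships the published 16-node / 28-edge subgraph around the
sulfonylurea drug Glyburide and type 2 diabetes mellitus, in which every
hypothesis path has depth 2 (one intermediate: a similar drug, a shared
target gene, or a related phenotype).

```bash
cat > cfg.yaml <<EOF
use_glyburide_fixture: true
sources: [glyburide]
targets: [type_2_diabetes_mellitus]
depths: [2]
embedding: {k: 8, epochs: 30}
autoencoder: {epochs: 40}
seed: 7
out_dir: glyb_run
EOF
lbdrank run-all cfg.yaml
```

The stage manifest reports 16 nodes / 28 edges, exactly 14 depth-2 paths,
and a 1-path top-5% selection (`⌈0.05·14⌉ = 1`):

```
"graph":  {"nodes": 16, "edges": 28, ...}
"paths":  {"total": 14, "per_cell": {"type_2_diabetes_mellitus@d2": 14}, ...}
"rank":   {"ranked": 14, "top": 1, "percentile": 5.0}
```

and `glyb_run/ranked_paths.tsv` begins

```
# rank  path                                                                    path_score  path_score_full
1       glyburide—[resembles]—tolazamide—[treats]—type_2_diabetes_mellitus      0.797       0.797092364
2       glyburide—[resembles]—chlorpropamide—[treats]—type_2_diabetes_mellitus  0.792       0.791821852
3       glyburide—[resembles]—glimepiride—[treats]—type_2_diabetes_mellitus     0.789       0.789224963
```

Each row is a hypothesis chain; `path_score` is the mean θ of its two
triples, so rows near the top are the chains whose individual assertions
the scoring model considers most probable.  At this toy scale the
absolute θ values reflect the tiny training set; the ranking, not the
magnitude, is the output of interest.

Library use mirrors the CLI:

```python
from lbdrank import (glyburide_fixture, enumerate_paths, train_complex,
                     train_autoencoder, extract_scoring_weights, score_triples,
                     score_and_rank)
from lbdrank.scorer import build_triple_vectors

g = glyburide_fixture()
paths = enumerate_paths(g, ["glyburide"], "type_2_diabetes_mellitus", depth=2)
len(paths)          # 14
table = train_complex(g)
vecs = build_triple_vectors(table, g)
h = extract_scoring_weights(train_autoencoder(vecs))
ranking = score_and_rank(paths, score_triples(vecs, h))
```

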