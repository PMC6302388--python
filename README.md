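# gane

Protein complex identification from protein–protein interaction (PPI)
networks via **G**O-**a**ttributed **n**etwork **e**mbedding.

Most complex-detection methods look for densely connected subgraphs of the
PPI network. `gane` additionally folds in functional annotations: every
protein is described by its GO-slim terms (biological process and
molecular function), and a joint embedding places proteins close together
when they either interact or share annotations. Complexes are then
assembled on the re-weighted network following the core–attachment model
of complex organisation: a densely connected core plus loosely bound
attachment proteins.

## Method

Given an undirected PPI graph `G = (V, E)` with adjacency `A` and a binary
protein × GO-slim matrix `O`, the protein attribute affinity matrix `S`
holds the cosine similarity of the binary annotation profiles,

    s_ij = Σ_k o_ik o_jk / (√Σ_k o_ik² · √Σ_k o_jk²).

Each protein gets a vector `φ_i ∈ R^d` minimising the bi-convex joint loss

    ℓ = Σ_{i≠j} a_ij ‖φ_i − φ_j‖²  +  λ Σ_{i≠j} (s_ij − φ_i·φ_j)²,

solved by exact block-coordinate descent (each row update is a d×d linear
solve, so the loss trace is monotonically non-increasing). Edges are then
re-weighted by embedding cosine similarity,

    w_ij = cos(φ_i, φ_j)  if a_ij = 1, else 0,

and complexes are detected in two phases:

1. **Cores** — all maximal cliques with ≥ 3 members (Tomita-pivot
   Bron–Kerbosch) are ranked by density score `Σ_{i,j∈clique} w_ij`; the
   top clique becomes a seed core, its members are subtracted from every
   overlapping candidate, undersized candidates are dropped, and the loop
   repeats, giving pairwise-disjoint clique cores.
2. **Attachments** — every graph-neighbor `p` of a core with correlation
   score `Σ_{k∈core} w_pk / |core|` strictly above the threshold θ is
   attached. A complex is a core plus its attachments.

Defaults: `d = 128`, `λ = 0.1`, `θ = 0.3`; complexes smaller than 3 are
filtered before evaluation. Predictions are scored against a reference
catalogue by neighborhood-affinity matching
(`NA(p,b) = |p∩b|²/(|p||b|) ≥ ω`, ω = 0.25: Precision / Recall / F-score)
and by the clustering-wise overlap metrics Sn / PPV / Acc = √(Sn·PPV),
with F-score + Acc as the composite comparison statistic.

A synthetic generator plants core–attachment complexes with coherent
GO-slim annotations plus configurable background noise, so the whole
pipeline is testable end to end without any downloads.

## Worked example

Simulate a small benchmark (5 planted complexes, 2% background edge
noise, 80% annotation coherence), detect, and evaluate:

```sh
cat > spec.yaml <<EOF
n_complexes: 5
core_size_range: [4, 6]
attachments_range: [1, 2]
background_nodes: 20
background_edge_p: 0.02
coherent_annotation_p: 0.8
seed: 7
EOF
gane simulate --spec spec.yaml --out-prefix bench
gane detect --edges bench.edges.tsv --go-slim bench.go_slim.tab \
            --dim 32 --seed 7 --out pred.txt
gane eval --pred pred.txt --ref bench.truth.txt
```

`pred.txt` holds one complex per line in the annotated dialect, core
members before the `|`, attachments after:

```
P00008 P00009 P00010 P00011 P00012 P00013 | P00014
P00028 P00029 P00030 P00031 P00032 P00033 | P00034 P00035 P00047
```

and `gane eval` prints:

```
n_predicted  5
n_reference  5
n_cp         5
n_cb         5
precision    1.0000
recall       1.0000
f_score      1.0000
sn           1.0000
ppv          1.0000
acc          1.0000
composite    2.0000
omega        0.2500
```

All 5 predicted complexes match a planted complex at NA ≥ 0.25 and vice
versa (`n_cp`, `n_cb`), so Precision = Recall = F-score = 1; the overlap
matrix is diagonal, so Sn = PPV = Acc = 1 and the composite (F + Acc)
reaches its maximum of 2. On this small, mildly noisy instance recovery
is perfect; harder settings (denser background, weaker coherence) lower
the scores. `gane sweep --param theta ...` grids one hyperparameter
(θ over 0.1–0.9, d over 32–224, λ over 10⁻⁵–10³) and tabulates composite
scores.

The same pipeline is available as a library:

```python
from gane import (SyntheticSpec, EmbeddingConfig, DetectionConfig,
                  generate, run_pipeline, evaluate)

network, annotations, truth = generate(SyntheticSpec(seed=7))
result = run_pipeline(network, annotations,
                      EmbeddingConfig(dim=32, seed=7), DetectionConfig())
print(evaluate(result.complexes, truth).format())
```

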