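# Methods

## Model

`gane` treats a PPI network as an attributed graph: vertices are proteins,
edges are observed physical interactions, and each protein carries a
binary GO-slim annotation profile. The working assumptions are the usual
ones for this family of methods: (i) real complexes appear as densely
connected regions of the interaction graph; (ii) members of a complex
tend to share function, so annotation similarity is corroborating
evidence; (iii) a complex is organised as a clique-like core plus
loosely attached peripheral proteins.

Only the biological-process (Bp) and molecular-function (Mf) GO aspects
are used as attributes. Cellular-component slim terms frequently *name*
complexes, so keeping them would leak the answer into the features; they
are excluded by default (`read_go_slim(keep_aspects=...)` can re-enable
them).

### Embedding

The joint loss over row vectors `φ_i ∈ R^d`

    ℓ = Σ_{i≠j} a_ij ‖φ_i − φ_j‖² + λ Σ_{i≠j} (s_ij − φ_i·φ_j)²

sums over ordered pairs with the diagonal excluded. Excluding `i = j` is a
deliberate modelling choice: `a_ii = 0` after self-loop removal makes the
topology term moot, and a diagonal attribute term `(s_ii − ‖φ_i‖²)²` would
turn the per-row subproblem from quadratic into quartic, destroying the
closed-form coordinate update the bi-convex structure affords. The printed
`(φ_i − φ_j)²` penalty is read as the squared Euclidean norm — the only
scalar-valued reading consistent with a loss function.

The optimizer is serial exact block-coordinate descent: holding all other
rows fixed, row i minimises an unconstrained convex quadratic whose
stationarity condition is the d×d system

    [deg_i I + λ Φ_{-i}ᵀΦ_{-i}] φ_i = Σ_j a_ij φ_j + λ Σ_{j≠i} s_ij φ_j.

A running Gram matrix `ΦᵀΦ` makes each row update O(d² + |N(i)|d + nd).
Distributed ADMM solvers for this objective exist, but a serial exact
solver gives two properties worth more at this scale: a provably
monotone loss trace (asserted in tests on every fit) and bit-for-bit
deterministic runs. If a row system is singular (possible for isolated
vertices at λ = 0) it falls back to a ridge-jittered least-squares solve
and logs the event.

Numerical choices:

* initialisation i.i.d. uniform on [−0.5/d, 0.5/d] from a seeded
  generator — small and symmetric so the first solves are well scaled;
* convergence when the relative loss change between sweeps drops below
  `tol` (default 1e-6) or after `max_sweeps` (default 50);
* the cosine of a zero vector is defined as 0 everywhere (weighting,
  correlation scores): zero annotation or a zero embedding row carries no
  evidence.

### Affinity

`S` is the plain binary cosine of annotation profiles. Unannotated
proteins get `s_ij = 0` against everyone, including themselves (0/0 is
resolved to "no evidence"); annotated proteins have `s_ii = 1`, though the
diagonal never enters the loss. `S` is materialised densely up to 2000
proteins and as CSR above that; both paths are tested for agreement.

### Detection

Maximal cliques (≥ 3 members) are enumerated with the pivoting
Bron–Kerbosch algorithm (networkx's `find_cliques`). Seed-core selection
re-sorts surviving candidates by density score *inside* the loop, i.e.
scores are recomputed after subtraction — candidates shrunk by an earlier
winner keep competing with their reduced member sets. Sorting ties are
broken by larger clique first, then lexicographically smallest member
list; the tie-break is what makes detection output byte-identical across
reruns. Subtraction can make two candidates identical; duplicates
collapse to one.

Attachment candidates are restricted to unweighted-graph neighbors of the
core, and attach on a strict `score > θ` comparison, whereas reference
matching uses `NA ≥ ω` — each follows its own defining formula. Negative
cosine weights are kept (they penalise density and correlation scores);
`--clamp-weights` floors them at 0 for users who prefer non-negative
weights. A protein may attach to several cores, so predicted complexes
can overlap even though cores cannot.

### Evaluation

Matching uses the neighborhood affinity score with inclusive threshold
`NA ≥ ω` (ω = 0.25). Degenerate conventions keep reports total: an empty
prediction set has Precision 0; F-score is 0 when Precision + Recall = 0;
PPV (and hence Acc) is 0 with a logged warning when predictions share no
protein with any reference complex. Both complex sets are size-≥3
filtered before scoring (configurable). `Acc² = Sn·PPV` holds exactly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `dim` (d) | 128 | embedding dimension; 32–224 is the sensible sweep range, results are not very sensitive within it |
| `lam` (λ) | 0.1 | topology/attribute trade-off; λ→0 is pure topological smoothing, large λ pure attribute factorisation |
| `theta` (θ) | 0.3 | attachment threshold on the mean core weight, in [0,1] |
| `omega` (ω) | 0.25 | NA matching threshold for evaluation |
| `tol`, `max_sweeps` | 1e-6, 50 | optimizer stopping rule |
| `min_clique_size` | 3 | minimum core (and complex) size |

The synthetic tests and the acceptance script use d = 32 rather than 128:
their instances have ~100 proteins and ≤ 12 planted complexes, for which
32 dimensions are already past the point of saturation, and the smaller
solve keeps each replicate under a second.

## Synthetic benchmark

`SyntheticSpec` plants K complexes, each a fully connected core (sizes
4–6 by default) plus 1–2 attachments. Every attachment is wired to a
random subset of its core (each member with probability 0.8), clamped to
be nonempty and *strict* — a fully wired attachment would merge with the
core into a larger clique, so one edge is removed in that case. This
keeps every planted core a maximal clique whenever no background edges
are added, which is what lets the noise-free recovery test demand exact
behaviour. Annotations are per-complex coherent term sets (3 terms from a
60-term vocabulary, each member annotated with probability 0.8 by
default) plus uniform background annotations (p = 0.01); background
proteins (40) and Erdős–Rényi background edges (p = 0.02) model
non-complex interactome context.

What the generator does **not** emulate: the heavy-tailed degree
distributions, annotation biases, and false-negative interaction rates of
real curated PPI datasets, nor overlapping cores. Passing the recovery
tests therefore shows the pipeline is implemented correctly and behaves
sensibly under controlled noise — not that it attains any particular
performance level on real interactomes.

Experiment sizes: recovery runs use 5 replicates of ~65–105 proteins;
the clique oracle uses 50 random G(12, 0.4) graphs; the metric oracle
100 random complex-set pairs over ≤ 200 proteins. These sizes were chosen
so every oracle can be an exhaustive or nested-loop reference
implementation while the whole suite stays fast.

The noisy-condition regression bound (mean F ≥ 0.90, Acc ≥ 0.90 at
background edge p = 0.02, coherence 0.8) was pinned from a baseline run
of `recovery_experiment` at those settings (observed mean F = 0.990,
Acc = 0.972 over seeds 101–105) with a margin for seed sensitivity.

## Known limitations

* The optimizer converges to a local optimum of a bi-convex problem;
  different seeds can give different embeddings (all tested properties
  hold for every seed, but complex-level output may differ on ambiguous
  instances).
* Dense `S` costs O(n²) memory; beyond the CSR switch-over the embedding
  row updates still touch full affinity rows, so very large networks
  (≫ 10⁴ proteins) would need a sparsity-aware update not implemented
  here.
* No ID mapping between protein naming systems: the edge list defines
  the universe, annotation rows for unknown proteins are ignored, and
  unannotated proteins get zero attribute rows.
* Evaluation implements the matching and clustering-wise metrics only;
  GO-enrichment significance of predictions is out of scope.
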