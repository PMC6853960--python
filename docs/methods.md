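# Methods

## The model

`mpdisnet` treats disease–disease similarity as a representation-learning
problem on a heterogeneous network `G = (V, E, F)` with three node types
(disease, miRNA, gene) and four undirected, unweighted layers
(disease–miRNA, miRNA–gene, disease–gene, gene–gene/PPI). Proteins are
identified with their coding genes so the interactome contributes
gene–gene edges; this is what lets the meta-paths M1/M2/M3 step through
the PPI layer without a fourth node type.

**Walks.** A meta-path constrains each step of a random walk to one node
type; the transition law is uniform over the current node's neighbors of
the required type and zero elsewhere. Only symmetric meta-paths (first
type = last type) are supported: they recurse, so a walk of `s` pattern
traversals has `s(l−1)+1` nodes when it never dead-ends. A walk reaching
a node with no neighbor of the required type is truncated and flagged
incomplete; truncated walks of at least two nodes stay in the corpus
(they are genuinely observed context), bare one-node walks are dropped.
No teleportation, restarts or non-backtracking constraints exist in the
transition law, so immediate backtracking inside a gene–gene–gene segment
is permitted.

**Embedding.** The heterogeneous skip-gram objective stratifies contexts
by type: window contexts of a center node are grouped by the context's
type, and the per-type softmax is approximated with negative sampling
from a type-restricted unigram-count distribution raised to
`noise_exponent`. One shared table holds center and context vectors. For
a pair (v, c) with negatives u₁..u_M the objective is
`log σ(x_c·x_v) + Σ log σ(−x_u·x_v)`; the updates used are its exact
gradients applied by stochastic gradient ascent (the per-target factor is
`(I[u=c] − σ(x_u·x_v))`, which the tests verify against central finite
differences). All per-pair gradients are computed from the pre-update
vectors, word2vec-style.

**Similarity and evaluation.** Disease vectors from several meta-paths
are fused by literal concatenation, without per-block L2 normalization
(normalizing would reweight meta-paths; the default stays literal).
Cosine similarity ranks unordered disease pairs; ties break
lexicographically. The miRNA-overlap baseline is the Jaccard index of the
two diseases' miRNA neighbor sets, with 0 for two empty sets ("no
evidence" is not "identical"). AUROC uses the tie-corrected rank
statistic; AUPR uses the non-interpolated step estimator (recorded in the
metrics output). The negative class is never synthesized silently —
labels must contain negatives, or `sample_negative_pairs` draws a seeded
1:1 complement and the seed is reported.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| steps_per_walk | 50 | full meta-path traversals per walk → 251-node M1 walks |
| walks_per_node | 1000 | walks attempted per disease |
| dimension | 128 | embedding width (32 in the desk-scale benchmarks) |
| window | 5 | context radius in walk positions, each side |
| negatives (M) | 5 | noise draws per observed pair |
| noise_exponent | 0.75 | unigram-count damping for the noise distribution |
| learning_rate | 0.025 → 1e−4 | linear decay across all updates |
| logit_max | 6 | clamp on \|x_u·x_v\| inside σ; keeps updates finite |
| epochs | 5 | passes over the shuffled pair stream |

Embedding width, window, negatives and the noise exponent follow the
standard skip-gram/word2vec conventions for node embeddings; the walk
configuration (50 traversals, 1000 walks/disease) is the reference
configuration for real-scale networks. Initialization is uniform in
`[−0.5/d, 0.5/d)` from the config seed.

## Numerical and determinism choices

* Neighbor lists are stored sorted; one seeded generator per corpus is
  consumed in node-then-walk order, so corpora are byte-reproducible.
* Training determinism: vocabulary order is sorted, pair enumeration is
  vectorized in a fixed order, per-epoch shuffling and negative draws
  come from the same seeded generator, and the SGD kernel is sequential.
  The kernel is numba-compiled scalar code (float64, no fastmath) with an
  identical pure-numpy fallback.
* A negative drawn equal to its own context is redrawn once and then
  kept; on tiny vocabularies this avoids unbounded rejection loops and
  the residual bias is negligible.
* Heterogeneous edge-list files need not order their columns
  consistently; endpoint types are inferred by constraint propagation,
  with declared column order as the last-resort default and a hard error
  on genuine type conflicts. Self-loop lines are dropped with a warning.
* Degenerate inputs: cosine with a zero (missing-embedding) vector is 0;
  diseases missing from one meta-path's corpus get a zero block in the
  fused vector rather than being dropped; labeled pairs naming unknown
  diseases are dropped with a logged count.
* The pipeline derives per-stage seeds as `global_seed + stage_index` in
  execution order, writes outputs through temp files renamed on success
  (a failed stage leaves a `.partial` file), and fingerprints outputs
  with SHA-256 in the manifest.

## Synthetic data: what it does and does not show

The generator plants a partition: disease clusters own private gene pools
and (channel-dependent) miRNA pools, with higher within-cluster than
cross-cluster Bernoulli attachment (defaults: 2 clusters × 5 diseases,
40 miRNAs, 60 genes; within-layer rates 0.5–0.8, cross 0.02, PPI within
0.3). The `gene-mediated` channel gives every disease private miRNAs —
no pair ever shares one, so the overlap baseline is exactly
uninformative — while those miRNAs still target the cluster's genes, so
M1/M3 walks carry the signal. Desk-scale recovery (AUROC > 0.9 for the
fused embedding vs ≈ 0.5 for the baseline, at dim 32, 10 traversals,
200 walks/disease) demonstrates the mechanism the method is designed to
exploit under controlled conditions.

What passing these benchmarks does **not** show: real disease–miRNA and
interactome data are scale-free-ish, noisy and ascertainment-biased
(well-studied miRNAs/proteins have inflated degree), disease vocabularies
are heterogeneous, and the clinical "truth" for comorbidity is itself a
biased sample. The planted-partition generator models none of that —
structure, not scale or degree distribution, is emulated — so synthetic
AUROC values do not transfer to real networks.

## Known limitations

* Only symmetric meta-paths; no weighted or biased (p,q-style) walks.
* One embedding table (no separate output vectors) and no frequent-node
  subsampling, keeping the implementation faithful to the single-matrix
  objective above.
* Similarity for diseases absent from every layer rests on zero vectors,
  i.e. they rank last rather than being excluded; interpret accordingly.
* Path enumeration (`explain`) is exhaustive and deterministic; on dense
  real networks an explicit `limit` is essential since M1/M2 instance
  counts grow combinatorially.
* t-SNE layouts are seeded but remain visualization plumbing; distances
  in the 2-D projection carry no quantitative claim.
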