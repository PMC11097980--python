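# Methods

## Model and assumptions

The package predicts unobserved drug–gene associations from a binary
bipartite interaction graph. The modeling assumptions are those of
embedding-based collaborative filtering on graphs:

1. association is binary — curated interaction lists carry no reliable
   strength information, so duplicate input rows collapse to one edge;
2. the association matrix has low effective rank — drugs acting on a family
   of targets and genes hit by a family of drugs form dense blocks, so a
   rank-`t` SVD of the normalized adjacency captures the global structure;
3. co-interaction is the only signal — no chemical structure, sequence, or
   expression features enter the model. Each node is represented purely by a
   learnable ID embedding, and those two matrices are the *only* parameters:
   the propagation stack has no weights.

The two propagation views (observed adjacency with edge dropout; rank-`t`
reconstruction in factored form) produce per-layer embedding stacks anchored
at the same base embeddings. The cross-view InfoNCE term treats the two
views of the same node as a positive pair and, within a batch, the views of
different active nodes as negatives. Because the parameters are just the
embedding matrices, the whole objective is differentiated in closed form
(reverse-mode through the layer chain, with the adjoints of each propagation
operator), and the analytic gradients are verified against central finite
differences in the test suite. Optimization is Adam.

The contrastive denominator runs over the *batch's* active nodes rather
than all nodes: a full-graph softmax costs O(N²) per step and contradicts
the design goal of keeping the contrastive stage as cheap as the base GCN.
Node inactivation (each batch member kept with probability `cl_keep_prob`)
further decorrelates the negatives between steps. Negatives for the ranking
loss are re-sampled uniformly per epoch from each anchor drug's
non-associated genes.

## Parameters

| name | default | meaning |
|---|---|---|
| `d` | 256 | embedding width; the sensitivity sweep grid is {64,…,1024} |
| `L` | 2 | propagation layers; deeper stacks oversmooth |
| `t` | 5 | SVD rank of the global view |
| `tau` | 0.2 | InfoNCE temperature |
| `lambda1` | 0.1 | contrastive weight |
| `lambda2` | 1e-5 | L2 weight on the embedding matrices |
| `edge_dropout` | 0.25 | per-edge drop probability on the observed view (train only) |
| `cl_keep_prob` | 0.5 | per-batch node activity probability in the contrastive term |
| `neg_per_pos` | 1 | sampled non-edges per observed pair in the hinge loss |
| `node_drop_rate` | 0.1 | row-zeroing fraction of the node-dropping ablation |
| `epochs` | 300 | full-data setting; the synthetic suite default is 50 |
| `learning_rate` | 1e-3 | Adam step size |

The activation is LeakyReLU with slope 0.5 (an identity option exists so
linear-algebra oracles can check propagation exactly). Initialization is
Xavier-uniform, seeded. The randomized SVD uses 10 oversamples and 4 power
iterations; each factor pair's sign is fixed by making the largest-magnitude
entry of the `U` column positive, so decompositions are test-stable.

## Evaluation protocol

Known edges are split into k folds (sizes differing by at most one); each
fold's model trains only on its training edges — including the SVD view,
which is recomputed per fold so held-out edges never leak into the
augmentation. Held-out edges are scored against an equal number of
uniformly sampled non-edges ("balanced negatives"; the ratio is
configurable). AUC uses the tie-aware rank statistic (exact, equivalent to
the Mann–Whitney U), AUPR uses step integration of the precision–recall
curve with stable index tie-breaks, and the thresholded metrics binarize at
the top-`n_pos` rule (as many predicted positives as actual positives),
which is deterministic and invariant to score scaling; a fixed-threshold
alternative is exposed. Candidate ranking for a query node excludes its
known partners and sorts the rest by score, descending, stable in index.

## Synthetic benchmark: what it does and does not show

The generator plants a block structure: drugs and genes are assigned
round-robin to `n_blocks` communities, and a pair is associated with
probability `p_in` within a block and `p_out` across. Defaults
(m=100, n=60, 4 blocks, p_in=0.3, p_out=0.02) give ~540 edges — dense
enough for stable metrics, small enough that a full ablation suite runs in
minutes on one CPU; the suite trains 50 epochs on these fixtures (the
300-epoch default targets database-scale data).

This emulates the modular co-interaction structure of curated drug–gene
databases, but not their heavy-tailed degree distributions, their scale
(tens of thousands of nodes), annotation noise, or any chemistry/biology
beyond block membership. Passing the synthetic suite therefore demonstrates
mechanical correctness and that the learning signal is actually exploited —
not database-scale accuracy.

One property of the default generator deserves emphasis: conditional on the
planted blocks, all within-block non-training pairs are exchangeable, so no
scorer can beat the two-valued block-membership rule. With 20% of edges
held out and balanced uniform negatives, a held-out positive lies within a
block with probability ≈0.83 while a sampled negative does with ≈0.19,
which caps the achievable AUC at roughly 0.81 (the acceptance script
computes this ceiling as `planted_oracle_auc_ceiling` alongside the model's
actual recovery). Held-out AUC on this benchmark should be read against
that ceiling, not against 1.0.

## Numerical choices and degenerate inputs

- Zero-degree rows/columns of the adjacency normalize to zero rows (no
  NaN/Inf); such nodes receive no messages and keep their base embeddings'
  contribution only.
- Cosine similarity of a zero-norm embedding row is defined as 0, with zero
  gradient through that row.
- The InfoNCE softmax is stabilized by subtracting the row maximum.
- Edge dropout rescales surviving entries by 1/(1−rate), so the dropped
  operator is unbiased in expectation; evaluation mode never drops.
- A non-finite loss aborts training with the offending component named.
- Checkpoints carry a version header; truncated or mismatched files raise
  instead of loading silently.

## Open design choices

Several protocol details admit multiple reasonable readings; the package
fixes them as follows and exposes each as configuration where sensible:
symmetric degree normalization (the standard choice for bipartite GCN
propagation); layer chaining feeds each layer the previous layer's outputs
(the only reading under which a 2-layer stack is nontrivial); dropout acts
on adjacency entries, and is disabled at inference; `t`, oversampling and
power-iteration counts for the SVD are package defaults; evaluation
negatives are balanced uniform samples per fold; hinge negatives are
re-sampled each epoch; the gene-anchored symmetric ranking pass exists but
is off by default.

## Known limitations

- Training materializes dense embedding-gradient matrices, so memory scales
  as O((m+n)·d); database-scale graphs (10⁴–10⁵ nodes) fit, but far larger
  graphs would need sharded updates.
- The batch-wise contrastive denominator makes the loss value (not the
  minimizer structure) depend on batch size.
- `rank_candidates` re-propagates embeddings per call; for bulk queries,
  compute final embeddings once via `compute_final_embeddings`.
- No literature mining or orthogonal data validate ranked candidates; the
  ranking is a screening aid, not evidence of interaction.
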