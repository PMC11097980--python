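# svdgcl

Self-supervised graph contrastive learning for drug–gene association
prediction, built for computational drug-repurposing work: given a curated
binary edge list of known drug–gene interactions (e.g. a DGIdb export), the
model ranks the unobserved pairs most likely to be real associations.

## Model

The data are a bipartite graph with `m` drugs, `n` genes and a binary
incidence matrix `A`. Each node carries a learnable embedding
(`E⁽ᵈ⁾ ∈ ℝ^{m×d}`, `E⁽ᵍ⁾ ∈ ℝ^{n×d}`); these are the model's only parameters.

- **Observed view.** A symmetric degree-normalized adjacency
  `Ã = D_d^{-1/2} A D_g^{-1/2}` drives `L` rounds of neighbor aggregation
  `z⁽ᵈ⁾_l = σ(p(Ã) z⁽ᵍ⁾_{l-1})`, `z⁽ᵍ⁾_l = σ(p(Ã)ᵀ z⁽ᵈ⁾_{l-1})`, with edge
  dropout `p(·)` during training and LeakyReLU `σ`. Final embeddings sum all
  layers: `e = Σ_{l=0}^{L} z_l`.
- **Global view.** A rank-`t` truncated randomized SVD `Ã ≈ U_t S_t V_tᵀ`
  gives a globally smoothed reconstruction; embeddings are propagated over it
  in factored form (`Â` is never materialized), yielding per-layer `h_l`.
- **Contrastive term.** An InfoNCE loss with temperature `τ` pulls each
  node's `z_l` toward its own `h_l` and away from the other active batch
  nodes', layer by layer, for drugs and genes separately. Per batch each node
  is randomly inactivated with probability `1 − keep_prob`.
- **Ranking term.** Association scores are inner products
  `P_ij = ⟨e_i⁽ᵈ⁾, e_j⁽ᵍ⁾⟩`; training minimizes the margin-1 pairwise hinge
  `Σ max(0, 1 − P_pos + P_neg)` over observed pairs vs. sampled non-edges.
- **Joint objective.** `L = L_r + λ₁(L_s⁽ᵈ⁾ + L_s⁽ᵍ⁾) + λ₂‖Θ‖₂²`, optimized
  with Adam. Ablation variants swap the global view for edge perturbation,
  node dropping, random-walk subgraphs, drop the contrastive term entirely,
  or reduce to plain matrix factorization.

Evaluation follows the standard link-prediction protocol: k-fold CV over the
known edges, scoring each held-out fold against balanced uniformly sampled
non-edges, with AUC, AUPR, Recall, Precision and F1 (thresholded at the
top-`n_pos` rule), plus top-k candidate ranking for case-study queries.

## Worked example

```python
import numpy as np
from svdgcl import (SyntheticSpec, generate_synthetic_graph, make_cv_folds,
                    TrainConfig, train, evaluate_fold, rank_candidates)

spec = SyntheticSpec(m=100, n=60, n_blocks=4, p_in=0.3, p_out=0.02, seed=0)
graph, drug_blocks, gene_blocks = generate_synthetic_graph(spec)
print(f"graph: {graph.m} drugs x {graph.n} genes, {graph.n_edges} associations")

fold = make_cv_folds(graph, k=5, seed=0)[0]          # 20% of edges held out
train_graph = graph.subgraph_with_edges(fold.train_edges)
ckpt, log = train(train_graph, TrainConfig(epochs=50, seed=0))
print(f"epoch 1  total loss: {log[0]['total']:.1f}")
print(f"epoch 50 total loss: {log[-1]['total']:.1f}")

report = evaluate_fold(ckpt, graph, fold)
print(f"held-out AUC: {report.auc:.4f}  AUPR: {report.aupr:.4f}  F1: {report.f1:.4f}")

for gene_id, score in rank_candidates(ckpt, graph, "D0000", top_k=5):
    print(f"  {gene_id}  {score:7.3f}")
```

prints

```
graph: 100 drugs x 60 genes, 549 associations
epoch 1  total loss: 268.8
epoch 50 total loss: 63.0
held-out AUC: 0.7683  AUPR: 0.7280  F1: 0.7273
  G0056    0.653
  G0028    0.591
  G0004    0.588
  G0035    0.579
  G0036    0.527
```

The loss drops by ~4x over 50 epochs; the held-out AUC of 0.77 sits close to
the ~0.81 Bayes ceiling of this generator (block membership is the only
learnable signal, and sampled negatives share blocks with held-out positives
~19% of the time). Four of the five top-ranked novel genes for drug `D0000`
belong to its planted block.

The same workflow is available from the shell:

```bash
svdgcl simulate --out edges.tsv --m 100 --n 60
svdgcl train --edges edges.tsv --out run/ --epochs 50
svdgcl predict --checkpoint run/checkpoint.npz --edges edges.tsv --query D0000 --top 15
svdgcl cv --edges edges.tsv --k 5 --out cv_report.tsv
svdgcl suite ablate --out ablation/
```

For a real DGIdb export, pass your own two-column TSV (drug id, gene id) to
`train`/`cv`; identifiers are preserved verbatim in all outputs.

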